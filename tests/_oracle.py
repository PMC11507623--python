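"""Brute-force re-derivation of every QC statistic by direct per-locus
enumeration, written independently of the package's qc_core logic.

Works on raw allele tuples pulled out of the shared data containers; all
classification and arithmetic below is re-implemented from the stated
rules, not delegated, so agreement with run_qc is a genuine cross-check.
"""

from __future__ import annotations


def _alleles(call):
    """Return a sorted tuple of alleles, or None for a missing call."""
    return None if call.missing else tuple(sorted(call.alleles))


def pair_class(a, b):
    if a is None or b is None:
        return "MISSING"
    if a[0] != a[1] or b[0] != b[1]:
        return "PARENT_HET"
    return "POLYMORPHIC" if a[0] != b[0] else "MONOMORPHIC"


def off_class(a, b, f):
    # pre: pair_class(a, b) == "POLYMORPHIC"
    if f is None:
        return "MISSING"
    parental = {a[0], b[0]}
    if set(f) - parental:
        return "NON_PARENTAL"
    return "HET_TRUE" if set(f) == parental else "HOM_PARENTAL"


def oracle_family(family, marker_ids, thr):
    """Re-derive all statistics and statuses for one cross family.

    Returns a dict with keys: pair (pm, mc, polymorphism, het1, het2,
    classes) and offspring (list of per-offspring dicts).
    """
    p1 = {m: _alleles(family.parent1.calls[m]) for m in marker_ids}
    p2 = {m: _alleles(family.parent2.calls[m]) for m in marker_ids}
    tm = len(marker_ids)

    classes = {m: pair_class(p1[m], p2[m]) for m in marker_ids}
    pm = [m for m in marker_ids if classes[m] == "POLYMORPHIC"]
    mc_pair = sum(1 for m in marker_ids if classes[m] == "MISSING")
    poly = 100.0 * len(pm) / (tm - mc_pair) if tm - mc_pair else None

    def het_pct(par):
        miss = sum(1 for m in marker_ids if par[m] is None)
        het = sum(1 for m in marker_ids
                  if par[m] is not None and par[m][0] != par[m][1])
        return 100.0 * het / (tm - miss) if tm - miss else None

    het1, het2 = het_pct(p1), het_pct(p2)

    out = {
        "pm": len(pm), "mc_pair": mc_pair, "polymorphism": poly,
        "het1": het1, "het2": het2, "classes": classes, "offspring": [],
    }

    for rec in family.offspring:
        f = {m: _alleles(rec.calls[m]) for m in marker_ids}
        ocls = {m: off_class(p1[m], p2[m], f[m]) for m in pm}
        lhet = sum(1 for c in ocls.values() if c == "HET_TRUE")
        lnpa = sum(1 for c in ocls.values() if c == "NON_PARENTAL")
        mc_inf = sum(1 for c in ocls.values() if c == "MISSING")
        mc_all = sum(1 for m in marker_ids if f[m] is None)
        denom = len(pm) - mc_inf
        hyb = 100.0 * lhet / denom if denom else None
        npa = 100.0 * lnpa / len(pm) if pm else None
        miss = 100.0 * mc_all / tm if tm else None

        hets = [h for h in (het1, het2) if h is not None]
        if hets and max(hets) > thr.max_parent_het_pct:
            status = "Undetermine: Parent Heterozygous"
        elif poly is None or poly < thr.min_polymorphism_pct:
            status = "Undetermine: Parent not polymorphic"
        elif (miss is not None and miss > thr.max_missing_pct) or hyb is None:
            status = "Undetermine: missing data"
        elif hyb >= thr.min_hybridity_pct:
            status = "TRUE CROSS"
        else:
            status = "SELF"

        out["offspring"].append({
            "classes": ocls, "lhet": lhet, "lnpa": lnpa,
            "mc_inf": mc_inf, "mc_all": mc_all, "hybridity": hyb,
            "non_parental": npa, "missing": miss, "status": status,
        })
    return out


def oracle_marker_efficiency(families, marker_ids):
    """Per-marker efficiency across families by direct counting."""
    tc = len(families)
    out = {}
    for m in marker_ids:
        fm = 0
        for fam in families:
            a = _alleles(fam.parent1.calls[m])
            b = _alleles(fam.parent2.calls[m])
            if pair_class(a, b) == "POLYMORPHIC":
                fm += 1
        out[m] = (fm, tc, 100.0 * fm / tc if tc else None)
    return out
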