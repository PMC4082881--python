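"""Independent brute-force re-implementations used as test oracles.

These deliberately avoid the package's rule engine: every published rule
is re-stated here as a flat predicate over a plain evidence dictionary,
evaluated in the documented precedence.  The acceptance suite compares the
engine against these on large random inputs.
"""

from __future__ import annotations


def oracle_assign_class(b: dict) -> int:
    """Five-class decision from a flat evidence bundle.

    Keys: dbsnp, kg (frequencies or None), inhouse (int), genotype
    ('het'/'hom'/'hemi'), has_partner (bool), recessive_only (bool),
    silent (bool), n_missense_path (0-4), n_splice_loss (0-5),
    n_splice_nochange (0-5), cases (int), functional, same_codon, near,
    benign_reported (bools), match ('match'/'mismatch'/'unknown'),
    fit ('fits'/'violates'), seg ('fits'/'conflicts'/'uninformative').
    """
    freqs = [f for f in (b["dbsnp"], b["kg"]) if f is not None]
    polymorphic = any(f >= 0.01 for f in freqs)
    hom_or_comphet = b["genotype"] == "hom" or (
        b["genotype"] == "het" and b["has_partner"]
    )
    exempt = hom_or_comphet and not polymorphic

    pclass = None
    # class 1: common polymorphism
    if not exempt and (polymorphic or b["inhouse"] >= 4):
        pclass = 1
    # class 2: unlikely
    if pclass is None:
        band = any(0.001 <= f < 0.01 for f in freqs)
        controls_band = 2 <= b["inhouse"] <= 3
        splice_benign = b["silent"] and b["n_splice_nochange"] == 5
        if (not exempt and (band or controls_band)) or splice_benign or b["benign_reported"]:
            pclass = 2
    gates = b["fit"] == "fits" and b["match"] == "match" and b["seg"] != "conflicts"
    # class 5: certain
    if pclass is None and gates:
        if b["cases"] >= 2 or b["functional"] or b["same_codon"]:
            pclass = 5
    # class 4: likely
    if pclass is None and gates:
        if (
            b["cases"] >= 1
            or b["n_missense_path"] >= 2
            or b["n_splice_loss"] >= 4
            or b["near"]
        ):
            pclass = 4
    # class 3: uncertain (rare, no segregation conflict)
    if pclass is None:
        rare = all(f <= 0.001 for f in freqs) and (exempt or b["inhouse"] <= 1)
        if rare and b["seg"] != "conflicts":
            pclass = 3
        else:
            pclass = 2
    # recessive-het cap
    lone_recessive_het = (
        b["genotype"] == "het" and not b["has_partner"] and b["recessive_only"]
    )
    if lone_recessive_het:
        pclass = min(pclass, 3)
    return pclass


def oracle_filter(b: dict) -> str:
    """Sequential re-application of the three written removal rules.

    Keys: dbsnp, kg, inhouse, hom_or_comphet (bool), silent (bool),
    n_splice_loss (int).  Returns the removal stage or 'candidate'.
    """
    freqs = [f for f in (b["dbsnp"], b["kg"]) if f is not None]

    def freq_hit(t):
        return any(f >= t for f in freqs)

    exempt = b["hom_or_comphet"] and not freq_hit(0.01)
    if (freq_hit(0.01) or b["inhouse"] >= 4) and not exempt:
        return "stage1"
    if (freq_hit(0.001) or b["inhouse"] >= 2) and not exempt:
        return "stage2_freq"
    if b["silent"] and b["n_splice_loss"] < 4:
        return "stage2_silent"
    return "candidate"
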