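"""Sign-concordance classification of mRNA-lncRNA co-expression.

For each mRNA-lncRNA pair and each condition (maturation, ischemic injury)
the two Pearson trend coefficients are reduced to signs with a dead zone of
half-width tau (default 0.1): R >= tau is "+", R <= -tau is "-", anything
smaller in magnitude carries no sign.  Equal defined signs give a
synergistic verdict, opposite defined signs an inverse verdict.  The final
label is synergistic or inverse only when both conditions agree; any mixed
or sign-indeterminate combination is inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PairRelationship",
    "condition_relationship",
    "final_relationship",
    "eligible_genes",
    "classify_pairs",
]

SYNERGISTIC = "synergistic"
INVERSE = "inverse"
UNDEFINED = "undefined"
INCONCLUSIVE = "inconclusive"


@dataclass(frozen=True)
class PairRelationship:
    gene: str
    mrna: str
    lnc: str
    r_mrna_maturation: float | None
    r_lnc_maturation: float | None
    r_mrna_injury: float | None
    r_lnc_injury: float | None
    verdict_maturation: str
    verdict_injury: str
    label: str
    tau: float

    def __post_init__(self) -> None:
        both_syn = self.verdict_maturation == self.verdict_injury == SYNERGISTIC
        both_inv = self.verdict_maturation == self.verdict_injury == INVERSE
        expected = SYNERGISTIC if both_syn else INVERSE if both_inv else INCONCLUSIVE
        if self.label != expected:
            raise ValueError(f"label {self.label!r} inconsistent with verdicts")


def _sign(r: float | None, tau: float) -> int | None:
    """+1 / -1 / None under the tau dead zone; with tau = 0, sign(0) is +."""
    if r is None:
        return None
    if r >= tau:
        return 1
    if r <= -tau:
        return -1
    return None


def condition_relationship(r_mrna: float | None, r_lnc: float | None,
                           tau: float = 0.1) -> str:
    """Per-condition verdict from the two trend coefficients."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    s1, s2 = _sign(r_mrna, tau), _sign(r_lnc, tau)
    if s1 is None or s2 is None:
        return UNDEFINED
    return SYNERGISTIC if s1 == s2 else INVERSE


def final_relationship(verdict_maturation: str, verdict_injury: str) -> str:
    """Cross-condition reconciliation of the two per-condition verdicts."""
    if verdict_maturation == verdict_injury == SYNERGISTIC:
        return SYNERGISTIC
    if verdict_maturation == verdict_injury == INVERSE:
        return INVERSE
    return INCONCLUSIVE


def classify_pairs(pairs, tau: float = 0.1) -> list[PairRelationship]:
    """Classify an iterable of pair records.

    Each record is a mapping with keys ``gene, mrna, lnc, r_mrna_maturation,
    r_lnc_maturation, r_mrna_injury, r_lnc_injury`` (R values may be None
    for an undefined trend).
    """
    out = []
    for rec in pairs:
        vm = condition_relationship(rec["r_mrna_maturation"], rec["r_lnc_maturation"], tau)
        vi = condition_relationship(rec["r_mrna_injury"], rec["r_lnc_injury"], tau)
        out.append(
            PairRelationship(
                gene=rec["gene"],
                mrna=rec["mrna"],
                lnc=rec["lnc"],
                r_mrna_maturation=rec["r_mrna_maturation"],
                r_lnc_maturation=rec["r_lnc_maturation"],
                r_mrna_injury=rec["r_mrna_injury"],
                r_lnc_injury=rec["r_lnc_injury"],
                verdict_maturation=vm,
                verdict_injury=vi,
                label=final_relationship(vm, vi),
                tau=tau,
            )
        )
    return out


def eligible_genes(pair_labels: list[PairRelationship]) -> list[str]:
    """Genes with at least one non-inconclusive (inverse or synergistic) pair,
    in first-appearance order."""
    seen: list[str] = []
    for p in pair_labels:
        if p.label != INCONCLUSIVE and p.gene not in seen:
            seen.append(p.gene)
    return seen
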