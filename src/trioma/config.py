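"""Fixed analysis thresholds, collected in one configurable object."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class AnalysisConfig:
    """Thresholds of the integrated analysis.

    Attributes
    ----------
    slr_cut_mrna_lnc:
        |SLR| cut calling an mRNA/lncRNA probe differentially expressed
        relative to the baseline (log2 units).
    slr_cut_mirna:
        Same for miRNA probes.
    mirna_signal_floor:
        Minimum mean background-subtracted intensity for a miRNA probe to
        count as detected (arbitrary intensity units).
    bidirectional_window_bp:
        Maximum TSS-to-TSS distance (bp) for a head-to-head divergent lncRNA
        to be classed bidirectional to a coding gene.
    promoter_bp:
        Extent of the promoter interval upstream of a TSS (bp) used for
        sub-region labelling.
    sign_threshold:
        tau: minimum |R| for a Pearson trend coefficient to carry a sign in
        the synergistic/inverse relationship call.
    min_genes_per_mirna:
        A miRNA enters the regulatory network only if it targets at least
        this many of the eligible genes.
    ct_absent_cut:
        qPCR C_T above which an assay is called absent (cycles).
    max_cycles:
        qPCR run length; "Undetermined" maps here inside presence calls.
    alpha_weak, alpha_strong:
        Significance grades: single mark for p < alpha_weak, double mark for
        p < alpha_strong.
    presence_alpha:
        p-value a sample-vs-NTC t-test must beat for a presence call.
    one_sample_tail:
        "one" (toward the observed deviation) or "two".
    """

    slr_cut_mrna_lnc: float = 1.0
    slr_cut_mirna: float = 0.6
    mirna_signal_floor: float = 300.0
    bidirectional_window_bp: int = 1000
    promoter_bp: int = 1000
    sign_threshold: float = 0.1
    min_genes_per_mirna: int = 2
    ct_absent_cut: float = 35.0
    max_cycles: float = 40.0
    alpha_weak: float = 0.10
    alpha_strong: float = 0.05
    presence_alpha: float = 0.01
    one_sample_tail: str = "one"

    def __post_init__(self) -> None:
        for name in (
            "slr_cut_mrna_lnc",
            "slr_cut_mirna",
            "mirna_signal_floor",
            "bidirectional_window_bp",
            "promoter_bp",
            "ct_absent_cut",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sign_threshold < 0:
            raise ValueError("sign_threshold must be >= 0")
        if not self.alpha_strong < self.alpha_weak:
            raise ValueError("alpha levels must satisfy alpha_strong < alpha_weak")
        if self.one_sample_tail not in ("one", "two"):
            raise ValueError("one_sample_tail must be 'one' or 'two'")


DEFAULT_CONFIG = AnalysisConfig()
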