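"""Configuration objects for the synthetic generator and the pipeline.

The synthetic generator plants a toy genome of promoter CpG islands in three
chromatin classes — *low* (no marks), *bivalent* (H3K4me3 + H3K27me3 with
H3K4me1 elevated over the CGI body, the "trivalent" state) and *active*
(H3K4me3 with the typical bimodal H3K4me1: high shores, low body) — plus a
paired perturbed condition in which bivalent promoters lose H3K27me3 and
planted subsets lose (biloss) or gain (bigain) their shore H3K4me1.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .errors import ConfigError

MARKS = ("H3K4me1", "H3K4me3", "H3K27me3", "H3K27ac")
CLASSES = ("low", "bivalent", "active")
PATTERNS = ("typical_bimodal", "untypical_unimodal", "flat")
TRANSITIONS = ("biloss", "bigain", "none")

#: CGI length bounds for promoter CGIs (bp).
CGI_MIN_BP = 200
CGI_MAX_BP = 5000

#: Minimum enhancer midpoint-to-TSS distance (bp).
ENHANCER_MIN_TSS_DISTANCE = 5000


def _default_proportions() -> dict:
    return {"low": 1.0 / 3.0, "bivalent": 1.0 / 3.0, "active": 1.0 / 3.0}


def _default_shape_params() -> dict:
    # (body plateau amplitude, shore shoulder peak amplitude), mean coverage.
    return {
        "low": {
            "H3K4me1": (0.5, 0.5),
            "H3K4me3": (0.5, 0.5),
            "H3K27me3": (0.5, 0.5),
            "H3K27ac": (0.5, 0.5),
        },
        "bivalent": {
            "H3K4me1": (10.0, 2.0),  # shore overridden per transition group
            "H3K4me3": (10.0, 4.0),
            "H3K27me3": (10.0, 6.0),
            "H3K27ac": (0.5, 0.5),
        },
        "active": {
            "H3K4me1": (2.0, 10.0),
            "H3K4me3": (14.0, 6.0),
            "H3K27me3": (0.5, 0.5),
            "H3K27ac": (0.5, 0.5),
        },
    }


def _default_transition_fractions() -> dict:
    return {"biloss": 0.25, "bigain": 0.25}


def _default_expression_levels() -> dict:
    # Constant per-class baseline expression (TPM-like); tissue-specific
    # genes get `specific_high` in the target tissue and `specific_off`
    # elsewhere.  The active class sits at the within-tissue 90th percentile
    # so only planted genes exceed it.
    return {"low": 0.5, "bivalent": 5.0, "active": 50.0}


def _default_de_effects() -> dict:
    # log2FC ~ N(mu, sigma) per transition group in the KO-vs-WT contrast.
    return {"biloss": (0.5, 0.3), "bigain": (2.0, 0.3), "none": (0.0, 0.2)}


def _default_enhancer_amps() -> dict:
    # mark -> (baseline amplitude, condition-2 amplitude at enhancers of
    # tissue-specific genes); emulates enhancer activation accompanying
    # tissue-specific induction.
    return {"H3K4me1": (8.0, 9.5), "H3K27ac": (8.0, 11.0)}


@dataclass
class NoiseConfig:
    """Negative-binomial coverage noise.

    dispersion
        NB size parameter r (variance = mu + mu^2/r).  ``None`` disables
        noise entirely (tracks equal the deterministic shape).
    mean_scale
        Multiplier on all shape means, emulating sequencing depth.
    """

    dispersion: float | None = 10.0
    mean_scale: float = 1.0


@dataclass
class SyntheticConfig:
    """Full parameterization of the synthetic genome, tracks and expression."""

    n_chroms: int = 2
    chrom_length: int = 4_200_000
    n_promoters: int = 600
    class_proportions: dict = field(default_factory=_default_proportions)
    cgi_length_range: tuple = (400, 1200)
    flank: int = 1000
    baseline: float = 0.5
    shape_params: dict = field(default_factory=_default_shape_params)
    #: bivalent H3K4me1 shoulder amplitude (high, low); biloss promoters
    #: start high and drop, bigain promoters start low and rise.
    transition_shore: tuple = (8.0, 2.0)
    shore_sigma: float = 200.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    transition_fractions: dict = field(default_factory=_default_transition_fractions)
    conditions: tuple = ("WT", "KO")

    n_tissues: int = 6
    n_specific_per_tissue: int = 15
    #: bivalent background genes are expressed in this many tissues only
    #: (poised genes are tissue-restricted), giving the class its high Tau
    n_expressed_tissues_bivalent: int = 2
    expression_levels: dict = field(default_factory=_default_expression_levels)
    specific_high: float = 1000.0
    specific_off: float = 0.1
    #: log2-scale sd of multiplicative expression noise; 0 keeps the
    #: planted construction exact (with noise the planted genes still meet
    #: both selection criteria, but background genes in the top expression
    #: decile enter the selection too — an inherent property of the
    #: percentile rule at few tissues)
    expression_noise_sd: float = 0.0

    de_effects: dict = field(default_factory=_default_de_effects)
    de_p_transition: float = 1e-6
    de_lfc_cut: float = 1.2
    de_p_cut: float = 0.1

    #: omit planted enhancers (shrinks intergenic spacing ~4x; promoter
    #: geometry and signal are unchanged) for runs that never touch them
    place_enhancers: bool = True
    enhancer_length: int = 800
    enhancer_amps: dict = field(default_factory=_default_enhancer_amps)
    #: per-gene, per-condition sd of enhancer amplitude around its mean —
    #: real enhancer activity varies between loci, so induced and basal
    #: distributions overlap rather than separate perfectly
    enhancer_amp_sd: float = 1.5

    seed: int = 0

    def __post_init__(self):
        if isinstance(self.noise, dict):
            self.noise = NoiseConfig(**self.noise)
        self.cgi_length_range = tuple(self.cgi_length_range)
        self.conditions = tuple(self.conditions)
        self.transition_shore = tuple(self.transition_shore)
        self.validate()

    def validate(self) -> None:
        errs = []
        if self.n_chroms < 1:
            errs.append("n_chroms must be >= 1")
        if self.n_promoters < 1:
            errs.append("n_promoters must be >= 1")
        total = sum(self.class_proportions.get(c, 0.0) for c in CLASSES)
        if abs(total - 1.0) > 1e-9:
            errs.append(
                f"class_proportions must sum to 1 (got {total!r})"
            )
        lo, hi = self.cgi_length_range
        if lo < CGI_MIN_BP or hi > CGI_MAX_BP or lo > hi:
            errs.append(
                "cgi_length_range must lie within "
                f"[{CGI_MIN_BP}, {CGI_MAX_BP}] bp and be ordered, got ({lo}, {hi})"
            )
        if self.flank <= 0:
            errs.append("flank must be positive")
        for cls, marks in self.shape_params.items():
            for mark, (body, shore) in marks.items():
                if body < 0 or shore < 0:
                    errs.append(f"negative amplitude for {cls}/{mark}")
        if self.noise.dispersion is not None and self.noise.dispersion <= 0:
            errs.append("noise dispersion must be > 0 (or None for noiseless)")
        if self.noise.mean_scale <= 0:
            errs.append("noise mean_scale must be > 0")
        frac = sum(self.transition_fractions.values())
        if frac > 1.0 + 1e-9 or any(v < 0 for v in self.transition_fractions.values()):
            errs.append("transition_fractions must be nonnegative and sum to <= 1")
        if self.n_tissues < 2:
            errs.append("n_tissues must be >= 2")
        if len(self.conditions) != 2:
            errs.append("exactly two conditions are required")
        if errs:
            raise ConfigError(errs)

    # -- layout geometry --------------------------------------------------
    @property
    def slot_length(self) -> int:
        """bp reserved per promoter: CGI + shores + enhancer + spacing.

        The spacing keeps every planted enhancer midpoint > 5 kb from both
        the promoter's own TSS and the next promoter's TSS; without
        enhancers a short intergenic gap suffices.
        """
        extra = 10_500 if self.place_enhancers else 500
        return int(self.cgi_length_range[1] + 2 * self.flank + extra)

    def capacity_per_chrom(self) -> int:
        usable = self.chrom_length - 2 * self.flank
        return max(usable // self.slot_length, 0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ConfigError([f"unknown simulate option(s): {sorted(extra)}"])
        return cls(**d)
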