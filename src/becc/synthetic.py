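"""Synthetic expression compendia with planted marker structure.

The generator emulates the geometry a universal cell-type marker shows
in a large heterogeneous compendium: every sample carries a latent
target-cell abundance; genes expressed by all target cells ("universal"
markers) are high exactly in the samples that contain target cells, so
all universal markers share one Boolean pattern and are mutually
Boolean-equivalent.  "Subset" markers are expressed only when the target
cells additionally run a subset program, so subset-high implies
universal-high but not conversely — the asymmetric implication geometry.
Noise genes are bimodal but independent of the latent abundance.

Expression is on the log2 scale with a bimodal low/high structure per
gene (defaults mimic RMA-normalized array output: low mean 4.0, high
mean 9.0, within-state SD 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix, ProbeAnnotation

__all__ = ["SyntheticConfig", "Truth", "generate_compendium",
           "generate_pure_population", "synthetic_annotation"]

UNIVERSAL = "universal"
SUBSET = "subset"
NOISE = "noise"


@dataclass
class SyntheticConfig:
    """Parameters of the planted-marker compendium.

    Attributes
    ----------
    n_samples, n_universal, n_subset, n_noise
        Compendium dimensions (samples; universal-marker, subset-marker
        and unrelated noise probes).
    frac_positive
        Fraction of samples containing target cells at all; the rest sit
        near zero abundance.  Positive samples draw abundance uniformly
        on (abundance_floor, 1].
    abundance_floor
        Lower edge of the positive-abundance component.
    purity_cutoff
        Samples with abundance above this are flagged "pure target".
    low_mean, high_mean, sd
        Bimodal log2 levels and within-state standard deviation.
    subset_prevalence
        Probability that a target-positive sample also runs the subset
        program (drives the asymmetric implications).
    contamination
        Fraction of opposite-state samples in pure populations (sorting
        impurity); gives purified datasets a realistic thin far tail.
    rng_seed
        Generator seed; identical config + seed reproduces bit-identical
        matrices.
    """

    n_samples: int = 1000
    n_universal: int = 20
    n_subset: int = 10
    n_noise: int = 2000
    frac_positive: float = 0.4
    abundance_floor: float = 0.05
    purity_cutoff: float = 0.95
    low_mean: float = 4.0
    high_mean: float = 9.0
    sd: float = 0.7
    subset_prevalence: float = 0.4
    contamination: float = 0.03
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.high_mean <= self.low_mean:
            raise ValueError("high_mean must exceed low_mean")
        if self.sd <= 0:
            raise ValueError("sd must be > 0")
        if not (0 < self.subset_prevalence < 1):
            raise ValueError("subset_prevalence must be in (0, 1)")
        if not (0 < self.frac_positive < 1):
            raise ValueError("frac_positive must be in (0, 1)")
        if not (0 <= self.contamination < 0.5):
            raise ValueError("contamination must be in [0, 0.5)")
        for name in ("n_samples", "n_universal", "n_subset", "n_noise"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Truth:
    """Ground truth of a generated compendium."""

    labels: dict[str, str]            # probe id -> universal/subset/noise
    abundance: np.ndarray             # latent target-cell abundance/sample
    pure: np.ndarray                  # boolean purity flag per sample
    subset_active: np.ndarray = field(default=None)  # subset-program flag

    def probes_with_label(self, label: str) -> list[str]:
        return [p for p, lab in self.labels.items() if lab == label]


def _probe_ids(cfg: SyntheticConfig) -> tuple[list[str], list[str], list[str]]:
    uni = [f"UNI{i:03d}_at" for i in range(cfg.n_universal)]
    sub = [f"SUB{i:03d}_at" for i in range(cfg.n_subset)]
    noi = [f"NSE{i:04d}_at" for i in range(cfg.n_noise)]
    return uni, sub, noi


def generate_compendium(cfg: SyntheticConfig) -> tuple[ExpressionMatrix, Truth]:
    """Generate a heterogeneous compendium with planted markers.

    Per sample a latent abundance f is drawn: with probability
    ``1 - frac_positive`` near zero (target cells absent), otherwise
    uniform on (abundance_floor, 1].  Universal probes emit the high
    level in target-positive samples and the low level otherwise; subset
    probes emit high only in target-positive samples whose subset
    program is active; noise probes are bimodal with a per-probe random
    mixing fraction, independent of f.  Gaussian log2 noise (``sd``) is
    added everywhere.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_samples
    positive = rng.random(n) < cfg.frac_positive
    f = np.zeros(n)
    f[positive] = rng.uniform(cfg.abundance_floor, 1.0, positive.sum())
    subset_active = positive & (rng.random(n) < cfg.subset_prevalence)

    uni_ids, sub_ids, noi_ids = _probe_ids(cfg)
    probe_ids = uni_ids + sub_ids + noi_ids
    span = cfg.high_mean - cfg.low_mean

    values = np.empty((len(probe_ids), n))
    row = 0
    for _ in uni_ids:
        level = np.where(positive, cfg.high_mean, cfg.low_mean)
        values[row] = level + rng.normal(0.0, cfg.sd, n)
        row += 1
    for _ in sub_ids:
        level = np.where(subset_active, cfg.high_mean, cfg.low_mean)
        values[row] = level + rng.normal(0.0, cfg.sd, n)
        row += 1
    for _ in noi_ids:
        mix = rng.uniform(0.2, 0.8)
        high = rng.random(n) < mix
        level = cfg.low_mean + span * high
        values[row] = level + rng.normal(0.0, cfg.sd, n)
        row += 1

    matrix = ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=[f"S{i:05d}" for i in range(n)],
        values=values,
        mask=np.zeros_like(values, dtype=bool),
        platform_tag="synthetic",
    )
    labels = {p: UNIVERSAL for p in uni_ids}
    labels.update({p: SUBSET for p in sub_ids})
    labels.update({p: NOISE for p in noi_ids})
    truth = Truth(labels=labels, abundance=f, pure=f > cfg.purity_cutoff,
                  subset_active=subset_active)
    return matrix, truth


def generate_pure_population(
    cfg: SyntheticConfig, population: str = "target", n_samples: int | None = None
) -> tuple[ExpressionMatrix, Truth]:
    """Generate a purified-population dataset (all samples one state).

    ``population="target"`` draws every sample at abundance ~ 1 (all
    cells are target cells), ``"other"`` at abundance ~ 0.  A small
    ``contamination`` fraction of samples carries the opposite state,
    mimicking sorting impurity.  In the target population subset probes
    stay bimodal (prevalence < 1), which is what makes them measurably
    more variable than universal probes in purified data.
    """
    if population not in ("target", "other"):
        raise ValueError("population must be 'target' or 'other'")
    rng = np.random.default_rng(cfg.rng_seed + (1 if population == "target" else 2))
    n = n_samples if n_samples is not None else cfg.n_samples

    contaminated = rng.random(n) < cfg.contamination
    if population == "target":
        positive = ~contaminated
        f = np.where(positive, rng.uniform(cfg.purity_cutoff, 1.0, n), 0.0)
    else:
        positive = contaminated
        f = np.where(positive, rng.uniform(cfg.purity_cutoff, 1.0, n), 0.0)
    subset_active = positive & (rng.random(n) < cfg.subset_prevalence)

    uni_ids, sub_ids, noi_ids = _probe_ids(cfg)
    probe_ids = uni_ids + sub_ids + noi_ids
    span = cfg.high_mean - cfg.low_mean
    values = np.empty((len(probe_ids), n))
    row = 0
    for _ in uni_ids:
        level = np.where(positive, cfg.high_mean, cfg.low_mean)
        values[row] = level + rng.normal(0.0, cfg.sd, n)
        row += 1
    for _ in sub_ids:
        level = np.where(subset_active, cfg.high_mean, cfg.low_mean)
        values[row] = level + rng.normal(0.0, cfg.sd, n)
        row += 1
    for _ in noi_ids:
        mix = rng.uniform(0.2, 0.8)
        high = rng.random(n) < mix
        level = cfg.low_mean + span * high
        values[row] = level + rng.normal(0.0, cfg.sd, n)
        row += 1

    matrix = ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=[f"{population[0].upper()}{i:05d}" for i in range(n)],
        values=values,
        mask=np.zeros_like(values, dtype=bool),
        platform_tag=f"synthetic-pure-{population}",
    )
    labels = {p: UNIVERSAL for p in uni_ids}
    labels.update({p: SUBSET for p in sub_ids})
    labels.update({p: NOISE for p in noi_ids})
    truth = Truth(labels=labels, abundance=f, pure=f > cfg.purity_cutoff,
                  subset_active=subset_active)
    return matrix, truth


def synthetic_annotation(cfg: SyntheticConfig) -> ProbeAnnotation:
    """Probe -> gene-symbol map for a generated compendium.

    Universal probes are paired two-per-gene (UNI000_at and UNI001_at
    both map to gene UNIG000, etc.) to exercise probe-to-gene
    deduplication; subset and noise probes map one-to-one.
    """
    uni_ids, sub_ids, noi_ids = _probe_ids(cfg)
    mapping: dict[str, list[str]] = {}
    for i, p in enumerate(uni_ids):
        mapping[p] = [f"UNIG{i // 2:03d}"]
    for i, p in enumerate(sub_ids):
        mapping[p] = [f"SUBG{i:03d}"]
    for i, p in enumerate(noi_ids):
        mapping[p] = [f"NSEG{i:04d}"]
    return ProbeAnnotation(mapping)
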