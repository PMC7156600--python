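"""Run configuration for the full marker-mining pipeline."""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of a seed-driven marker-mining run.

    Attributes
    ----------
    seed_probe
        Probe id the equivalence expansion starts from.
    s_threshold, p_threshold
        Sparse-quadrant cutoffs for Boolean implications (S > s_threshold
        and p < p_threshold).
    expansion_steps
        Number of equivalence-expansion rounds (default 3; more rounds
        tend to accumulate noise).
    noise_margin
        Half-width of the intermediate band around each probe's
        threshold, in log2 units (0.5 = a twofold band).
    min_informative
        Minimum informative samples for a pair to be classified at all.
    null_pairs
        Number of random probe pairs used for the empirical score null.
    rng_seed
        Seed for the null-pair sampler.
    annotation_path, output_path
        Optional file locations carried for CLI runs.
    """

    seed_probe: str
    s_threshold: float = 3.0
    p_threshold: float = 0.1
    expansion_steps: int = 3
    noise_margin: float = 0.5
    min_informative: int = 20
    null_pairs: int = 100_000
    rng_seed: int = 0
    annotation_path: str | None = None
    output_path: str | None = None

    def __post_init__(self) -> None:
        if self.s_threshold <= 0:
            raise ValueError("s_threshold must be > 0")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.expansion_steps < 1:
            raise ValueError("expansion_steps must be >= 1")
        if self.noise_margin < 0:
            raise ValueError("noise_margin must be >= 0")
        if self.null_pairs < 1:
            raise ValueError("null_pairs must be >= 1")
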