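"""In-memory containers for expression data and probe annotation.

An :class:`ExpressionMatrix` stores log2-scale expression values for
probes (rows) by samples (columns).  Values are kept in a dense float
array; missing entries live in an explicit boolean mask rather than as
NaN, so every stored value is finite and downstream arithmetic never has
to guess what a NaN means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "ProbeAnnotation"]


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    dups: list[str] = []
    for i in ids:
        if i in seen:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValueError(f"duplicate {kind} ids: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Probes-by-samples matrix of log2 expression values.

    Parameters
    ----------
    probe_ids
        Unique row identifiers (probesets or gene symbols), file order.
    sample_ids
        Unique column identifiers, file order.
    values
        Array of shape ``(n_probes, n_samples)``; every entry finite.
        Entries flagged in ``mask`` carry an arbitrary placeholder.
    mask
        Boolean array, same shape; ``True`` marks a missing entry.
    platform_tag
        Free-text platform descriptor (e.g. "GPL570"); informational.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    mask: np.ndarray | None = None
    platform_tag: str = ""
    _probe_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.probe_ids, "probe")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.probe_ids), len(self.sample_ids))
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} != (probes, samples) {expected}"
            )
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != expected:
                raise ValueError("mask shape does not match values")
            self.mask = self.mask | ~np.isfinite(self.values)
        # keep stored values finite even under masked entries
        if self.mask.any():
            self.values = np.where(self.mask, 0.0, self.values)
        self._probe_index = {p: i for i, p in enumerate(self.probe_ids)}

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def probe_index(self, probe_id: str) -> int:
        try:
            return self._probe_index[probe_id]
        except KeyError:
            raise KeyError(f"unknown probe id: {probe_id!r}") from None

    def probe_values(self, probe_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(values, missing_mask)`` for one probe."""
        i = self.probe_index(probe_id)
        return self.values[i], self.mask[i]

    def observed(self, probe_id: str) -> np.ndarray:
        """Non-missing values of one probe, in sample order."""
        v, m = self.probe_values(probe_id)
        return v[~m]

    def dynamic_range(self, probe_id: str) -> float:
        """max - min of the probe's observed log2 values."""
        obs = self.observed(probe_id)
        if obs.size == 0:
            return float("nan")
        return float(obs.max() - obs.min())

    def subset_probes(self, probe_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.probe_index(p) for p in probe_ids]
        return ExpressionMatrix(
            probe_ids=[self.probe_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx].copy(),
            mask=self.mask[idx].copy(),
            platform_tag=self.platform_tag,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Dense DataFrame with NaN at masked entries."""
        vals = np.where(self.mask, np.nan, self.values)
        return pd.DataFrame(vals, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, platform_tag: str = ""
    ) -> "ExpressionMatrix":
        vals = df.to_numpy(dtype=float)
        return cls(
            probe_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            values=np.nan_to_num(vals, nan=0.0),
            mask=~np.isfinite(vals),
            platform_tag=platform_tag,
        )

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.probe_ids == other.probe_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.mask, other.mask)
            and np.allclose(
                np.where(self.mask, 0.0, self.values),
                np.where(other.mask, 0.0, other.values),
            )
        )


class ProbeAnnotation(Mapping[str, list]):
    """Mapping of probe id to zero or more gene symbols.

    Several probesets may map to one gene and a probeset may be
    unannotated (empty symbol list).
    """

    def __init__(self, mapping: Mapping[str, Sequence[str]] | None = None):
        self._map: dict[str, list[str]] = {}
        if mapping:
            for probe, symbols in mapping.items():
                self._map[str(probe)] = [str(s) for s in symbols]

    def __getitem__(self, probe: str) -> list[str]:
        return self._map[probe]

    def __iter__(self) -> Iterator[str]:
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    def symbols_for(self, probe: str) -> list[str]:
        """Gene symbols for a probe; empty list when unannotated/unknown."""
        return list(self._map.get(probe, []))

    def unique_genes(self, probes: Sequence[str]) -> list[str]:
        """Deduplicated gene symbols across probes, first-seen order."""
        out: list[str] = []
        seen: set[str] = set()
        for p in probes:
            for s in self.symbols_for(p):
                if s not in seen:
                    seen.add(s)
                    out.append(s)
        return out
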