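"""Per-well sequencing-depth normalisation by the median-of-ratios estimator.

For each antibody row the geometric mean across wells defines a pseudo-
reference sample; a well's size factor is the median over rows of the ratio
count / reference.  Rows containing any zero are excluded from the reference
(standard convention); an optional "poscounts" fallback uses the geometric
mean of positive counts only, for sparse plates.  Factors are re-centred to
geometric mean 1 so the intercept of the downstream count model stays
identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demux import UMICountMatrix


@dataclass
class SizeFactors:
    """Positive per-well depth factors, geometric mean 1 after centering."""

    factors: pd.Series  # index well_id

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            bad = list(self.factors.index[self.factors <= 0])
            raise ValueError(f"non-positive size factors for wells {bad}")

    def __getitem__(self, well: str) -> float:
        return float(self.factors[well])

    @property
    def log(self) -> pd.Series:
        return np.log(self.factors)

    def to_tsv(self, path) -> None:
        self.factors.rename("size_factor").rename_axis("well_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "SizeFactors":
        s = pd.read_csv(path, sep="\t", index_col=0)["size_factor"]
        s.index = s.index.astype(str)
        return cls(factors=s)


def _as_frame(counts) -> pd.DataFrame:
    if isinstance(counts, UMICountMatrix):
        return counts.counts
    return pd.DataFrame(counts)


def size_factors(counts, *, poscounts: bool = False, center: bool = True) -> SizeFactors:
    """Median-of-ratios size factors per well.

    Parameters
    ----------
    counts : UMICountMatrix or DataFrame
        Antibodies × wells non-negative counts.
    poscounts : bool
        With the default False, only rows positive in every well enter the
        pseudo-reference; True computes row geometric means over positive
        entries only (for plates where no row is all-positive) and takes the
        per-well median of ratios over rows with a finite reference.
    center : bool
        Rescale factors to geometric mean 1 (default).
    """
    df = _as_frame(counts)
    if df.shape[1] == 0:
        raise ValueError("no wells in count matrix")
    mat = df.to_numpy(dtype=float)
    if mat.shape[1] == 1:
        return SizeFactors(pd.Series([1.0], index=df.columns, name="size_factor"))
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    if poscounts:
        pos = mat > 0
        n_pos = pos.sum(axis=1)
        usable = n_pos > 0
        log_ref = np.full(mat.shape[0], -np.inf)
        log_ref[usable] = (
            np.where(pos, logs, 0.0).sum(axis=1)[usable] / n_pos[usable]
        )
        rows = usable
    else:
        rows = np.isfinite(logs).all(axis=1)
        if not rows.any():
            raise ValueError(
                "no antibody row is positive in every well; re-run with "
                "poscounts=True to use the positive-count fallback"
            )
        log_ref = logs.mean(axis=1)
    log_ratios = logs[rows] - log_ref[rows][:, None]
    # wells with zero count in a reference row contribute -inf ratios; the
    # median is taken over finite ratios per well
    factors = np.empty(mat.shape[1])
    for j in range(mat.shape[1]):
        col = log_ratios[:, j]
        finite = col[np.isfinite(col)]
        if finite.size == 0:
            raise ValueError(f"cannot estimate a size factor for well {df.columns[j]!r}")
        factors[j] = np.exp(np.median(finite))
    if center:
        factors /= np.exp(np.mean(np.log(factors)))
    return SizeFactors(pd.Series(factors, index=df.columns, name="size_factor"))


def normalized_counts(counts, factors: SizeFactors) -> pd.DataFrame:
    """Counts divided by their well's size factor (QC/plotting scale; the
    count model consumes the factors as offsets instead)."""
    df = _as_frame(counts)
    missing = [w for w in df.columns if w not in factors.factors.index]
    if missing:
        raise ValueError(f"size factors missing for wells {missing}")
    return df / factors.factors[df.columns]
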