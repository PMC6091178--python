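"""Guide-versus-genome Pearson correlation and absolute-value thresholding.

The screen is deliberately simple: for each guide gene, the sample Pearson
coefficient r against every gene in the matrix, then a hard cutoff on |r|
(the family screen uses |r| > 0.8, the network |r| > 0.6 by default).
No p-values or multiple-testing correction are computed - the procedure
thresholds the coefficient itself - and no rank-based alternative is
offered. Zero-variance profiles make r mathematically undefined; they are
marked as such (NaN in the table, ``None`` from the scalar function) and
can never pass a filter, rather than being coerced to r = 0, which would
corrupt the sign statistics downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from guidecoex.io import ExpressionMatrix, GuideGeneSet

__all__ = [
    "CorrelationTable",
    "ThresholdSpec",
    "correlate_guides",
    "filter_by_threshold",
    "pearson_correlation",
]

logger = logging.getLogger("guidecoex")

_MODES = ("absolute", "positive", "negative")


@dataclass(frozen=True)
class ThresholdSpec:
    """A cutoff tau in (0, 1] on the correlation coefficient.

    mode:
        "absolute" compares |r| to tau, "positive" requires r above tau,
        "negative" requires r below -tau.
    strict:
        True means ">" (the default, matching a "greater than" cutoff),
        False means ">=".
    """

    tau: float
    mode: str = "absolute"
    strict: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.tau <= 1.0):
            raise ValueError(f"tau must be in (0, 1], got {self.tau}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")

    def passes(self, r: float) -> bool:
        """Whether a defined coefficient r satisfies this threshold."""
        if np.isnan(r):
            return False
        if self.mode == "absolute":
            value = abs(r)
        elif self.mode == "positive":
            value = r
        else:  # negative
            value = -r
        return value > self.tau if self.strict else value >= self.tau


@dataclass
class CorrelationTable:
    """Guide x gene Pearson coefficients over ``n_samples`` gradient points.

    ``r`` is indexed by guide id (rows) and gene id (columns); undefined
    coefficients (a zero-variance profile on either side) are NaN.
    """

    r: pd.DataFrame
    n_samples: int
    zero_variance_genes: list[str] = field(default_factory=list)

    @property
    def guide_ids(self) -> list[str]:
        return list(self.r.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.r.columns)

    def value(self, guide_id: str, gene_id: str) -> float | None:
        """r(guide, gene), or None when undefined."""
        v = float(self.r.at[guide_id, gene_id])
        return None if np.isnan(v) else v

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: guide_id, gene_id, r (6 decimals), defined."""
        records = []
        for guide in self.guide_ids:
            row = self.r.loc[guide]
            for gene in self.gene_ids:
                v = float(row[gene])
                defined = not np.isnan(v)
                records.append(
                    {
                        "guide_id": guide,
                        "gene_id": gene,
                        "r": f"{v:.6f}" if defined else "NA",
                        "defined": "true" if defined else "false",
                    }
                )
        return pd.DataFrame.from_records(records)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def pearson_correlation(x, y) -> float | None:
    """Sample Pearson coefficient of two equal-length vectors (n >= 3).

    Returns None (undefined) when either vector has zero variance;
    symmetric in its arguments and invariant to affine rescaling.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 points, got {x.size}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.sum(xc * xc)))
    sy = float(np.sqrt(np.sum(yc * yc)))
    if sx == 0.0 or sy == 0.0:
        return None
    # np.sum over the elementwise product keeps r exactly symmetric in x, y
    r = float(np.sum(xc * yc) / (sx * sy))
    return max(-1.0, min(1.0, r))


def correlate_guides(matrix: ExpressionMatrix, guides: GuideGeneSet) -> CorrelationTable:
    """One row of r per guide over all genes in the matrix (guides included).

    Zero-variance genes are marked undefined (NaN) and logged. A guide id
    absent from the matrix is an error naming the missing id.
    """
    missing = [g for g in guides.gene_ids if g not in matrix]
    if missing:
        raise KeyError(f"guide gene id not in expression matrix: {missing[0]!r}")

    values = matrix.values
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.sum(centered * centered, axis=1))
    defined = norms > 0.0
    zero_var = [g for g, d in zip(matrix.gene_ids, defined) if not d]
    if zero_var:
        logger.info(
            "%d zero-variance gene(s) marked undefined (first: %s)",
            len(zero_var),
            zero_var[0],
        )

    # unit-normalized rows: r is then a plain dot product
    z = np.zeros_like(centered)
    z[defined] = centered[defined] / norms[defined, None]

    index = pd.Index(matrix.gene_ids)
    guide_pos = [index.get_loc(g) for g in guides.gene_ids]
    r = z[guide_pos] @ z.T
    np.clip(r, -1.0, 1.0, out=r)
    r[:, ~defined] = np.nan
    for k, pos in enumerate(guide_pos):
        if not defined[pos]:
            r[k, :] = np.nan
        else:
            r[k, pos] = 1.0  # guide against itself, exact

    frame = pd.DataFrame(r, index=guides.gene_ids, columns=matrix.gene_ids)
    return CorrelationTable(frame, n_samples=matrix.n_samples, zero_variance_genes=zero_var)


def filter_by_threshold(
    table: CorrelationTable, spec: ThresholdSpec, guide: str
) -> set[str]:
    """Gene ids whose r versus ``guide`` passes ``spec``.

    The guide itself is always excluded; undefined coefficients never pass.
    """
    if guide not in table.r.index:
        raise KeyError(f"unknown guide: {guide!r}")
    row = table.r.loc[guide]
    return {
        gene
        for gene, v in row.items()
        if gene != guide and not np.isnan(v) and spec.passes(float(v))
    }
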