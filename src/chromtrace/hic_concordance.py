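"""Concordance between imaging distance matrices and binned contact maps.

Proximity-ligation contact frequency and microscopy-measured spatial
distance are inversely related; a strong negative correlation between the
two, at matched genomic bins, validates reconstructed chromatin traces.
Contact matrices enter as plain-text dumps at the panel's bin width
(binary .hic/cooler processing is out of scope here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .distance_stats import DistanceMatrix, FoldChangeMatrix

__all__ = [
    "ContactMatrix",
    "ConcordanceResult",
    "ContactMatrixError",
    "read_contact_matrix",
    "write_contact_matrix",
    "contact_matrix_from_array",
    "align_bins",
    "distance_contact_correlation",
    "fold_change_region_summary",
]


class ContactMatrixError(ValueError):
    pass


def _parse_label(label: str) -> tuple[str, int, int]:
    chrom, rest = label.split(":")
    start, end = rest.split("-")
    return chrom, int(start), int(end)


@dataclass
class ContactMatrix:
    """Dense symmetric contact-frequency matrix over equal-width sorted bins."""

    bins: pd.DataFrame  # chrom, start, end
    values: np.ndarray
    normalization: str = "NONE"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ContactMatrixError("contact matrix must be square")
        if v.shape[0] != len(self.bins):
            raise ContactMatrixError("bin table does not match matrix size")
        if np.nanmin(v) < 0:
            raise ContactMatrixError("negative contact frequencies are not allowed")
        if not np.allclose(v, v.T, rtol=1e-6, atol=1e-12, equal_nan=True):
            raise ContactMatrixError("contact matrix is asymmetric beyond tolerance")
        widths = self.bins["end"] - self.bins["start"]
        if widths.nunique() != 1:
            raise ContactMatrixError("bins must have equal width")
        starts = self.bins.groupby("chrom", sort=False)["start"]
        if not all(s.is_monotonic_increasing for _, s in starts):
            raise ContactMatrixError("bins must be sorted by start coordinate")
        self.values = v

    @property
    def bin_width(self) -> int:
        return int((self.bins["end"] - self.bins["start"]).iloc[0])

    def labels(self) -> list[str]:
        return [f"{r.chrom}:{r.start}-{r.end}" for r in self.bins.itertuples()]


def contact_matrix_from_array(
    values: np.ndarray, bins: pd.DataFrame, normalization: str = "NONE"
) -> ContactMatrix:
    return ContactMatrix(bins=bins.reset_index(drop=True), values=np.asarray(values, float), normalization=normalization)


def read_contact_matrix(path, fmt: str = "dense_tsv", normalization: str = "NONE") -> ContactMatrix:
    """Read a contact matrix from a text dump.

    ``dense_tsv``: square table, first row and column are ``chr:start-end``
    bin labels.  ``coo_tsv``: columns (bin1, bin2, count) with the same
    labels, upper triangle sufficient; the matrix is symmetrized.
    """
    if fmt == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ContactMatrixError("row and column bin labels differ")
        if df.isna().all(axis=None):
            raise ContactMatrixError("empty contact matrix")
        bins = pd.DataFrame(
            [_parse_label(l) for l in df.index], columns=["chrom", "start", "end"]
        )
        return ContactMatrix(bins=bins, values=df.to_numpy(dtype=float), normalization=normalization)
    if fmt == "coo_tsv":
        df = pd.read_csv(path, sep="\t")
        if not {"bin1", "bin2", "count"} <= set(df.columns):
            raise ContactMatrixError("coo_tsv needs columns bin1, bin2, count")
        labels = sorted(
            set(df["bin1"]) | set(df["bin2"]), key=lambda l: _parse_label(l)[1:]
        )
        index = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        v = np.zeros((n, n))
        for b1, b2, c in df.itertuples(index=False):
            i, j = index[b1], index[b2]
            v[i, j] = c
            v[j, i] = c
        bins = pd.DataFrame([_parse_label(l) for l in labels], columns=["chrom", "start", "end"])
        return ContactMatrix(bins=bins, values=v, normalization=normalization)
    raise ContactMatrixError(f"unknown format {fmt!r}")


def write_contact_matrix(cm: ContactMatrix, path) -> None:
    pd.DataFrame(cm.values, index=cm.labels(), columns=cm.labels()).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# alignment and correlation


def align_bins(distance: DistanceMatrix, contact: ContactMatrix) -> pd.DataFrame:
    """Pair (d_ij, c_ij) for i < j over bins common to both matrices.

    Bins are matched on exact (chrom, start, end); unmatched bins are
    dropped and counted, as are pairs missing a distance or contact value.
    Returns a DataFrame with columns i, j, distance, contact and attrs
    ``n_dropped_bins`` / ``n_excluded_pairs``.
    """
    if distance.bins is None:
        raise ContactMatrixError("distance matrix carries no bin coordinates")
    dkeys = [tuple(r) for r in distance.bins[["chrom", "start", "end"]].itertuples(index=False)]
    ckeys = [tuple(r) for r in contact.bins[["chrom", "start", "end"]].itertuples(index=False)]
    common = [k for k in dkeys if k in set(ckeys)]
    if not common:
        raise ContactMatrixError("no overlapping bins between distance and contact matrices")
    di = {k: i for i, k in enumerate(dkeys)}
    ci = {k: i for i, k in enumerate(ckeys)}
    n_dropped = (len(dkeys) - len(common)) + (len(ckeys) - len(common))
    rows = []
    excluded = 0
    for a in range(len(common)):
        for b in range(a + 1, len(common)):
            d = distance.values[di[common[a]], di[common[b]]]
            c = contact.values[ci[common[a]], ci[common[b]]]
            if np.isnan(d) or np.isnan(c):
                excluded += 1
                continue
            rows.append((a, b, float(d), float(c)))
    pairs = pd.DataFrame(rows, columns=["i", "j", "distance", "contact"])
    pairs.attrs["n_dropped_bins"] = n_dropped
    pairs.attrs["n_excluded_pairs"] = excluded
    return pairs


@dataclass
class ConcordanceResult:
    """Distance-vs-contact correlation over matched bin pairs."""

    r: float
    method: str
    transform: str
    n_pairs: int
    n_excluded: int
    p_value: float = float("nan")
    undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "method": self.method,
            "transform": self.transform,
            "n_pairs": self.n_pairs,
            "n_excluded": self.n_excluded,
            "p_value": self.p_value,
            "undefined": self.undefined,
        }


def distance_contact_correlation(
    pairs: pd.DataFrame,
    method: str = "pearson",
    transform: str = "identity",
    min_separation: int = 1,
) -> ConcordanceResult:
    """Correlate median distance with contact frequency across bin pairs.

    ``transform``: identity, ``log_contact`` (log10 contact only), or
    ``log_both``.  Zero contacts are excluded (and counted) under a log
    transform, never silently pseudocounted.  ``min_separation`` excludes
    near-diagonal pairs (|i − j| < min_separation).
    """
    sub = pairs[(pairs["j"] - pairs["i"]).abs() >= min_separation]
    d = sub["distance"].to_numpy(dtype=float)
    c = sub["contact"].to_numpy(dtype=float)
    excluded = int(pairs.attrs.get("n_excluded_pairs", 0)) + (len(pairs) - len(sub))
    if transform in ("log_contact", "log_both"):
        keep = c > 0
        excluded += int((~keep).sum())
        d, c = d[keep], c[keep]
        c = np.log10(c)
    if transform == "log_both":
        keep = d > 0
        excluded += int((~keep).sum())
        d, c = d[keep], c[keep]
        d = np.log10(d)
    elif transform not in ("identity", "log_contact"):
        raise ValueError(f"unknown transform {transform!r}")
    if len(d) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.allclose(d, d[0]) or np.allclose(c, c[0]):
        return ConcordanceResult(
            r=float("nan"), method=method, transform=transform,
            n_pairs=len(d), n_excluded=excluded, undefined=True,
        )
    if method == "pearson":
        r, p = stats.pearsonr(d, c)
    elif method == "spearman":
        r, p = stats.spearmanr(d, c)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ConcordanceResult(
        r=float(r), method=method, transform=transform,
        n_pairs=len(d), n_excluded=excluded, p_value=float(p),
    )


def fold_change_region_summary(
    fc: FoldChangeMatrix,
    block: tuple[int, int],
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Sign statistics of log2 fold-change entries inside vs outside a locus block.

    ``block`` is a half-open locus-index range [lo, hi).  An entry (i, j)
    is "inside" when both loci fall in the block and "outside" when
    neither does; straddling entries are ignored.  Reports the fraction of
    negative entries in each class with a seeded percentile bootstrap CI.
    """
    lo, hi = block
    n = len(fc.values)
    if not (0 <= lo < hi <= n):
        raise ValueError("block out of panel range")
    if hi - lo < 2:
        raise ValueError("block must span at least two loci")
    iu, ju = np.triu_indices(n, k=1)
    vals = fc.values[iu, ju]
    ok = ~np.isnan(vals)
    in_block = (iu >= lo) & (iu < hi) & (ju >= lo) & (ju < hi) & ok
    out_block = ((iu < lo) | (iu >= hi)) & ((ju < lo) | (ju >= hi)) & ok

    def frac_neg(sel: np.ndarray) -> float:
        if sel.sum() == 0:
            return float("nan")
        return float((vals[sel] < 0).mean())

    rng = np.random.default_rng(seed)

    def boot_ci(sel: np.ndarray) -> list[float]:
        v = vals[sel]
        if len(v) == 0:
            return [float("nan"), float("nan")]
        draws = rng.integers(0, len(v), size=(n_boot, len(v)))
        fr = (v[draws] < 0).mean(axis=1)
        return [float(np.percentile(fr, 2.5)), float(np.percentile(fr, 97.5))]

    return dict(
        block=[int(lo), int(hi)],
        inside_fraction_negative=frac_neg(in_block),
        inside_fraction_positive=1.0 - frac_neg(in_block) if in_block.sum() else float("nan"),
        outside_fraction_negative=frac_neg(out_block),
        outside_fraction_positive=1.0 - frac_neg(out_block) if out_block.sum() else float("nan"),
        inside_ci_negative=boot_ci(in_block),
        outside_ci_negative=boot_ci(out_block),
        n_inside=int(in_block.sum()),
        n_outside=int(out_block.sum()),
    )
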