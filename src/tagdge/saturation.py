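"""Sequencing-saturation analysis and expression-level distributions.

The saturation curve answers whether a library was sequenced deeply enough:
the number of genes detected (>= 1 unambiguously mapped tag) as a function
of subsampled depth should plateau well before the full library size.
Subsampling is nested — one random permutation of the clean-tag stream per
replicate, evaluated as prefixes — so each replicate's curve is exactly
non-decreasing by construction rather than only in expectation.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .de import categorize
from .errors import InputError
from .mapping import MappingResult
from .qc import CleanTagLibrary


def saturation_curve(
    clean: CleanTagLibrary,
    results: Mapping[str, MappingResult],
    depth_grid: list[int] | None = None,
    replicates: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Detected-gene counts at increasing subsampled depths.

    Every clean tag occupies stream positions (ambiguous and unknown tags
    included — depth is total clean tags, as sequenced), but only tags with
    a unique gene assignment can detect their gene.  Grid depths above the
    library size are clipped with a warning.  Returns a long DataFrame
    (replicate, depth, detected_genes).
    """
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    total = clean.clean_total
    if depth_grid is None:
        depth_grid = [round(total * i / 20) for i in range(21)]
    depth_grid = sorted(set(int(d) for d in depth_grid))
    if any(d < 0 for d in depth_grid):
        raise InputError("depths must be non-negative")
    if depth_grid and depth_grid[-1] > total:
        warnings.warn(
            f"depth grid exceeds library size {total}; clipping", stacklevel=2
        )
        depth_grid = sorted({min(d, total) for d in depth_grid})

    # integer-coded stream: gene code for uniquely mapped tags, -1 otherwise
    gene_codes: dict[str, int] = {}
    codes = np.empty(total, dtype=np.int64)
    pos = 0
    for tag, copies in clean.counts.items():
        res = results.get(tag)
        if res is not None and res.is_unique:
            code = gene_codes.setdefault(res.gene_id, len(gene_codes))
        else:
            code = -1
        codes[pos : pos + copies] = code
        pos += copies

    rng = np.random.default_rng(seed)
    rows = []
    n_genes = len(gene_codes)
    for rep in range(replicates):
        perm = rng.permutation(total)
        stream = codes[perm]
        # first occurrence position of each gene in this permutation
        first = np.full(n_genes, total + 1, dtype=np.int64)
        mapped = stream >= 0
        positions = np.nonzero(mapped)[0]
        if len(positions):
            genes_at = stream[positions]
            # reverse order so earlier positions overwrite later ones
            first[genes_at[::-1]] = positions[::-1]
        first_sorted = np.sort(first)
        for d in depth_grid:
            detected = int(np.searchsorted(first_sorted, d, side="left"))
            rows.append({"replicate": rep, "depth": d, "detected_genes": detected})
    return pd.DataFrame(rows, columns=["replicate", "depth", "detected_genes"])


def expected_detected_uniform(n_genes: int, copies_per_gene: int, depth: int) -> float:
    """Closed-form expected detected genes for a uniform library.

    With G genes of t copies each (T = G*t tags total), sampling d tags
    without replacement detects each gene with probability
    1 - C(T-t, d)/C(T, d) (hypergeometric inclusion).
    """
    from scipy.stats import hypergeom

    total = n_genes * copies_per_gene
    if depth > total:
        raise InputError("depth exceeds library size")
    p_missed = float(hypergeom.pmf(0, total, copies_per_gene, depth))
    return n_genes * (1.0 - p_missed)


def expression_level_histogram(tpm_values: pd.Series | np.ndarray) -> pd.DataFrame:
    """Logarithmic (decade) TPM bins plus the four abundance-category totals.

    Returns one row per bin with ``kind`` in {log10_bin, category}.  The
    category totals partition the genes: rare/low/moderate/high counts sum
    to the number of genes supplied.
    """
    values = np.asarray(tpm_values, dtype=float)
    if np.any(values < 0):
        raise InputError("TPM values must be non-negative")
    rows = []
    zero = int(np.sum(values == 0))
    rows.append({"kind": "log10_bin", "bin": "0", "genes": zero})
    positive = values[values > 0]
    if len(positive):
        lo = int(np.floor(np.log10(positive.min())))
        hi = int(np.floor(np.log10(positive.max())))
        for decade in range(lo, hi + 1):
            lo_v, hi_v = 10.0**decade, 10.0 ** (decade + 1)
            n = int(np.sum((positive >= lo_v) & (positive < hi_v)))
            rows.append(
                {"kind": "log10_bin", "bin": f"[{lo_v:g},{hi_v:g})", "genes": n}
            )
    for cat in ("rare", "low", "moderate", "high"):
        n = int(np.sum([categorize(v) == cat for v in values]))
        rows.append({"kind": "category", "bin": cat, "genes": n})
    return pd.DataFrame(rows, columns=["kind", "bin", "genes"])


def plot_saturation(curve: pd.DataFrame, path: str | Path) -> None:
    """Write a simple static saturation plot (mean curve plus replicates)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for rep, grp in curve.groupby("replicate"):
        ax.plot(grp["depth"], grp["detected_genes"], color="grey", alpha=0.4, lw=0.8)
    mean = curve.groupby("depth")["detected_genes"].mean()
    ax.plot(mean.index, mean.values, color="tab:blue", lw=2, label="mean")
    ax.set_xlabel("subsampled clean tags")
    ax.set_ylabel("detected genes")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
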