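"""Whole-organism abundance of host toxin-synthesizing enzymes.

Tissue-level transcript data give expression per gram of tissue on an
arbitrary normalized scale; multiplying by average tissue mass and summing
over tissues yields a rough whole-organism transcript quantity per gene.
This is a deliberately coarse estimate — transcript mass is not enzymatic
activity — but it separates enzymes that are essentially absent from the
body from those expressed at scale, which is what the ranking needs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class TissueExpression:
    """Gene × tissue expression matrix with per-tissue masses in grams."""

    expression: pd.DataFrame  # genes (rows) × tissues (cols), >= 0
    tissue_weights: pd.Series  # grams, > 0, indexed by tissue
    gene_ecs: dict[str, set[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if list(self.expression.columns) != list(self.tissue_weights.index):
            raise ValidationError("expression columns and tissue_weights index differ")
        neg = np.argwhere(self.expression.values < 0)
        if neg.size:
            i, j = neg[0]
            raise ValidationError(
                f"negative expression at gene {self.expression.index[i]}, "
                f"tissue {self.expression.columns[j]}"
            )
        bad = self.tissue_weights[self.tissue_weights <= 0]
        if not bad.empty:
            raise ValidationError(
                f"non-positive tissue weight for {list(bad.index)}"
            )


def write_expression(expr: TissueExpression, directory) -> None:
    """Write expression, tissue weights, and the gene → EC map as TSVs."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    expr.expression.rename_axis("gene").to_csv(directory / "expression.tsv", sep="\t")
    expr.tissue_weights.rename_axis("tissue").rename("grams").to_csv(
        directory / "tissue_weights.tsv", sep="\t"
    )
    pd.DataFrame(
        [
            {"gene": g, "ec_numbers": "|".join(sorted(ecs))}
            for g, ecs in sorted(expr.gene_ecs.items())
        ],
        columns=["gene", "ec_numbers"],
    ).to_csv(directory / "gene_ecs.tsv", sep="\t", index=False)


def load_expression(directory) -> TissueExpression:
    """Load a ``write_expression`` bundle; ``gene_ecs.tsv`` is optional."""
    from pathlib import Path

    from .errors import SchemaError

    directory = Path(directory)
    expr_path = directory / "expression.tsv"
    weights_path = directory / "tissue_weights.tsv"
    for p in (expr_path, weights_path):
        if not p.exists():
            raise SchemaError(f"missing input file: {p}")
    expression = pd.read_csv(expr_path, sep="\t", index_col="gene")
    weights = pd.read_csv(weights_path, sep="\t", index_col="tissue")["grams"]
    gene_ecs: dict[str, set[str]] = {}
    ec_path = directory / "gene_ecs.tsv"
    if ec_path.exists():
        df = pd.read_csv(ec_path, sep="\t", dtype=str, keep_default_na=False)
        gene_ecs = {
            row.gene: {t for t in row.ec_numbers.split("|") if t}
            for row in df.itertuples(index=False)
        }
    expr = TissueExpression(
        expression=expression, tissue_weights=weights, gene_ecs=gene_ecs
    )
    expr.validate()
    return expr


def organism_abundance(expr: TissueExpression) -> pd.DataFrame:
    """Weight-weighted transcript sum per gene.

    Returns a frame indexed by gene with columns ``abundance``
    (transcript-unit · grams) and ``log_abundance`` (log10(x + 1)).
    """
    expr.validate()
    weights = expr.tissue_weights.to_numpy(dtype=float)
    values = expr.expression.to_numpy(dtype=float) @ weights
    return pd.DataFrame(
        {
            "abundance": values,
            "log_abundance": np.log10(values + 1.0),
        },
        index=expr.expression.index.rename("gene"),
    )


def rank_toxin_enzymes(
    abundance: pd.DataFrame,
    toxin_to_genes: Mapping[str, Iterable[str]],
    k: int = 5,
) -> pd.DataFrame:
    """Rank host enzymes mapped to toxins by whole-organism abundance.

    One row per (toxin, gene); ``rank`` is the dense ascending rank of the
    gene among all distinct mapped genes, so the least abundant enzyme has
    rank 1. The bottom-k and top-k genes are flagged.
    """
    genes = sorted({g for gs in toxin_to_genes.values() for g in gs})
    missing = [g for g in genes if g not in abundance.index]
    if missing:
        raise ValidationError(f"genes absent from abundance table: {missing}")

    gene_ab = abundance.loc[genes, "abundance"]
    order = sorted(genes, key=lambda g: (gene_ab[g], g))
    rank = {g: i + 1 for i, g in enumerate(order)}
    n = len(order)
    bottom = set(order[:k])
    top = set(order[max(0, n - k):])

    rows = []
    for toxin, gs in toxin_to_genes.items():
        for g in gs:
            rows.append(
                {
                    "toxin_id": toxin,
                    "gene": g,
                    "abundance": float(gene_ab[g]),
                    "rank": rank[g],
                    "flag_bottom": g in bottom,
                    "flag_top": g in top,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["toxin_id", "gene", "abundance", "rank", "flag_bottom", "flag_top"],
    )
    return df.sort_values(["abundance", "gene", "toxin_id"], kind="stable").reset_index(
        drop=True
    )


def abundance_distribution(
    abundance: pd.DataFrame,
    highlight: set[str] | frozenset[str] = frozenset(),
    bins: int = 50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Histogram of log-abundance plus positions of highlighted genes.

    Returns ``(histogram, highlights)`` as plot-ready tables. The
    histogram has equal-width bins over the observed log-abundance range;
    a degenerate all-equal input occupies a single bin.
    """
    if abundance.empty:
        raise ValidationError("abundance table is empty")
    values = abundance["log_abundance"].to_numpy(dtype=float)
    lo, hi = float(values.min()), float(values.max())
    if math.isclose(lo, hi):
        hist = pd.DataFrame(
            {"bin_left": [lo - 0.5], "bin_right": [lo + 0.5], "count": [len(values)]}
        )
        edges = np.array([lo - 0.5, lo + 0.5])
    else:
        counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
        hist = pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )

    missing = sorted(set(highlight) - set(abundance.index))
    if missing:
        raise ValidationError(f"highlighted genes absent from abundance: {missing}")
    hi_rows = []
    for g in sorted(highlight):
        x = float(abundance.loc[g, "log_abundance"])
        idx = int(np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(hist) - 1))
        hi_rows.append({"gene": g, "log_abundance": x, "bin_index": idx})
    highlights = pd.DataFrame(hi_rows, columns=["gene", "log_abundance", "bin_index"])
    return hist, highlights


def detect_bimodality_dip(hist: pd.DataFrame, smooth: int = 3) -> bool:
    """Crude two-mode check: is there a dip between two histogram peaks?

    Smooths counts with a moving average, then asks whether some interior
    bin is lower than peaks on both sides. Intended for generator-level
    sanity checks, not as a statistical test.
    """
    counts = hist["count"].to_numpy(dtype=float)
    if len(counts) < 3:
        return False
    kernel = np.ones(smooth) / smooth
    sm = np.convolve(counts, kernel, mode="same")
    peak = int(np.argmax(sm))
    for j in range(len(sm)):
        lo, hi = sorted((j, peak))
        if hi - lo < 2:
            continue
        valley = sm[lo + 1:hi].min()
        # second mode must be substantial, not a noisy tail bin
        if sm[j] >= 0.2 * sm[peak] and valley < 0.5 * min(sm[peak], sm[j]):
            return True
    return False
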