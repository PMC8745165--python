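"""Toxin-level association analyses.

Two questions: does the number of bacteria able to synthesize a toxin
track its plasma concentration (in health or uremia)? And which toxins
share their producer bacteria — i.e., are made by the same community
members, typically because they sit on one pathway?

Concentrations span orders of magnitude across solutes, so the default
correlation is Spearman's rank correlation (Pearson available by config);
clustering defaults to Jaccard distance on binarized producer profiles
with average linkage, which groups toxins by shared producer *sets*
independent of reaction multiplicity.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, spearmanr

from .errors import ValidationError
from .capability import CapabilityMatrix
from .linkage import Link
from .reference_io import ToxinRecord


@dataclass
class CorrelationResult:
    condition: str  # normal | uremic
    coefficient: float | None
    p_value: float | None
    n: int
    status: str  # ok | insufficient_data | zero_variance


def concentration_correlation(
    summary: pd.DataFrame,
    toxins: Mapping[str, ToxinRecord],
    condition: str = "uremic",
    method: str = "spearman",
) -> CorrelationResult:
    """Rank correlation between producer-bacteria counts and concentration.

    Toxins with a missing concentration for the condition are dropped
    pairwise. Fewer than 3 usable pairs or a zero-variance vector yield an
    explicit no-result outcome rather than a number.
    """
    if condition not in ("normal", "uremic"):
        raise ValidationError(f"condition must be 'normal' or 'uremic', got {condition!r}")
    attr = "conc_normal" if condition == "normal" else "conc_uremic"

    xs, ys = [], []
    for row in summary.itertuples(index=False):
        tox = toxins.get(row.toxin_id)
        if tox is None:
            continue
        conc = getattr(tox, attr)
        if conc is None:
            continue
        xs.append(row.n_bacteria)
        ys.append(conc)

    n = len(xs)
    if n < 3:
        return CorrelationResult(condition, None, None, n, "insufficient_data")
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(condition, None, None, n, "zero_variance")

    if method == "spearman":
        rho, p = spearmanr(x, y)
    elif method == "pearson":
        rho, p = pearsonr(x, y)
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    return CorrelationResult(condition, float(rho), float(p), n, "ok")


def synthesis_profile(
    links: Iterable[Link],
    capability: CapabilityMatrix,
) -> pd.DataFrame:
    """Toxin × organism matrix of synthesis-capable reaction counts.

    A link contributes when its (organism, toxin) pair is classified as
    able to synthesize (class ``synthesize_only`` or ``both``).
    """
    counts: dict[tuple[str, str], int] = {}
    for l in links:
        cls = capability.get(l.organism_id, l.toxin_id)
        if cls in ("synthesize_only", "both"):
            key = (l.toxin_id, l.organism_id)
            counts[key] = counts.get(key, 0) + 1
    if not counts:
        return pd.DataFrame()
    toxins = sorted({t for t, _ in counts})
    orgs = sorted({o for _, o in counts})
    mat = pd.DataFrame(0, index=toxins, columns=orgs, dtype=int)
    for (t, o), c in counts.items():
        mat.loc[t, o] = c
    mat.index.name = "toxin_id"
    return mat


@dataclass
class ClusterResult:
    merges: np.ndarray  # scipy linkage matrix over kept rows
    labels: list[str]  # row ids in input order (all-zero rows dropped)
    leaf_order: list[str]
    ordered_matrix: pd.DataFrame
    cophenetic: pd.DataFrame  # square, labeled

    def cut(self, k: int) -> dict[str, int]:
        """Flat cluster labels from cutting the tree at k clusters."""
        flat = fcluster(self.merges, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(v) for v in flat)))


def toxin_cluster(
    profile: pd.DataFrame,
    distance: str = "jaccard",
    linkage_method: str = "average",
) -> ClusterResult:
    """Deterministic hierarchical clustering of toxin producer profiles.

    ``distance='jaccard'`` binarizes the profile first;
    ``distance='euclidean_log1p'`` uses log1p counts (pair with
    ``linkage_method='ward'``). All-zero rows are excluded with a warning.
    """
    if profile.empty:
        raise ValidationError("empty toxin-bacteria profile")
    keep = profile.sum(axis=1) > 0
    dropped = list(profile.index[~keep])
    if dropped:
        warnings.warn(f"excluding all-zero profile rows: {dropped}", stacklevel=2)
    profile = profile.loc[keep]
    if len(profile) < 2:
        raise ValidationError("need at least 2 toxins with nonzero profiles")

    if distance == "jaccard":
        data = profile.to_numpy() > 0
        dists = pdist(data, metric="jaccard")
    elif distance == "euclidean_log1p":
        data = np.log1p(profile.to_numpy(dtype=float))
        dists = pdist(data, metric="euclidean")
    else:
        raise ValidationError(f"unknown distance {distance!r}")

    merges = linkage(dists, method=linkage_method)
    order = [profile.index[i] for i in leaves_list(merges)]
    coph_condensed = cophenet(merges)
    coph = pd.DataFrame(
        squareform(coph_condensed), index=profile.index, columns=profile.index
    )
    return ClusterResult(
        merges=merges,
        labels=list(profile.index),
        leaf_order=order,
        ordered_matrix=profile.loc[order],
        cophenetic=coph,
    )


def merges_frame(result: ClusterResult) -> pd.DataFrame:
    """Plot-ready merge list: child indices, height, cluster size."""
    rows = [
        {
            "left": int(a),
            "right": int(b),
            "height": float(h),
            "size": int(s),
        }
        for a, b, h, s in result.merges
    ]
    return pd.DataFrame(rows, columns=["left", "right", "height", "size"])
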