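"""Bacterial community summaries from a taxon x sample count table.

This module starts downstream of sequencing: its input is a non-negative
count table (taxa as rows, samples as columns), a taxon -> phylum map, and
per-sample metadata (treatment, replicate, depth).  It provides phylum
aggregation, relative abundances, Gini-Simpson diversity, Bray-Curtis
dissimilarities and a PERMANOVA permutation test for community-structure
differences between treatment groups.

Phylum nomenclature is normalised to the current (post-2021) names; an
alias table maps the older synonyms (Actinobacteriota -> Actinomycetota,
Proteobacteria -> Pseudomonadota, ...) so mixed-vintage taxonomies
aggregate consistently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "PHYLUM_ALIASES",
    "CommunityTable",
    "normalize_phylum",
    "relative_abundance",
    "simpson_index",
    "bray_curtis",
    "permanova",
    "PermanovaResult",
]

#: Old -> new phylum nomenclature.
PHYLUM_ALIASES = {
    "Actinobacteriota": "Actinomycetota",
    "Actinobacteria": "Actinomycetota",
    "Proteobacteria": "Pseudomonadota",
    "Chloroflexi": "Chloroflexota",
    "Bacteroidetes": "Bacteroidota",
    "Firmicutes": "Bacillota",
    "Acidobacteria": "Acidobacteriota",
    "Gemmatimonadetes": "Gemmatimonadota",
    "Methylomirabiliota": "Methylomirabilota",
    "Planctomycetes": "Planctomycetota",
    "Verrucomicrobia": "Verrucomicrobiota",
}


def normalize_phylum(name: str) -> str:
    """Map a phylum name to the current nomenclature."""
    return PHYLUM_ALIASES.get(name, name)


@dataclass
class CommunityTable:
    """Taxon x sample counts with phylum map and sample metadata."""

    counts: pd.DataFrame  # taxa (rows) x samples (columns), integers >= 0
    taxon_phylum: dict[str, str]  # taxon -> phylum
    metadata: pd.DataFrame = field(default=None)  # sample -> treatment/replicate/depth

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.counts.sum(axis=0) <= 0).any():
            empty = self.counts.columns[self.counts.sum(axis=0) <= 0].tolist()
            raise ValueError(f"samples with zero total counts: {empty}")
        missing = [t for t in self.counts.index if t not in self.taxon_phylum]
        if missing:
            raise ValueError(f"taxa without phylum assignment: {missing[:5]}")

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def phylum_counts(self) -> pd.DataFrame:
        """Counts aggregated to (normalised) phylum level."""
        phyla = self.counts.index.map(
            lambda t: normalize_phylum(self.taxon_phylum[t])
        )
        return self.counts.groupby(phyla).sum()


def relative_abundance(table: CommunityTable, level: str = "phylum") -> pd.DataFrame:
    """Per-sample proportions at taxon or phylum level (columns sum to 1)."""
    if level == "phylum":
        counts = table.phylum_counts()
    elif level == "taxon":
        counts = table.counts
    else:
        raise ValueError(f"unknown aggregation level {level!r}")
    return counts / counts.sum(axis=0)


def simpson_index(counts, variant: str = "gini") -> float:
    """Simpson diversity of one sample's counts.

    ``variant="gini"`` (default) returns the Gini-Simpson index
    1 - sum(p_i^2), the probability that two randomly drawn reads belong
    to different taxa; ``variant="inverse"`` returns 1 / sum(p_i^2).
    """
    x = np.asarray(counts, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("total count must be > 0")
    p = x / total
    d = float(np.sum(p * p))
    if variant == "gini":
        return 1.0 - d
    if variant == "inverse":
        return 1.0 / d
    raise ValueError(f"unknown Simpson variant {variant!r}")


def bray_curtis(table: CommunityTable | pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity matrix between samples.

    Counts are converted to relative abundances first (no rarefaction),
    so BC(u, v) = sum|u_i - v_i| / sum(u_i + v_i) on proportions.
    """
    if isinstance(table, CommunityTable):
        props = relative_abundance(table, level="taxon")
    else:
        props = table / table.sum(axis=0)
    samples = props.columns
    if len(samples) < 2:
        raise ValueError("need at least 2 samples")
    dm = squareform(pdist(props.T.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(dm, index=samples, columns=samples)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    p: float
    n_perm: int
    n_groups: int
    n_samples: int


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """PERMANOVA pseudo-F from a squared-dissimilarity matrix and labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    groups = np.unique(labels)
    for g in groups:
        idx = np.flatnonzero(labels == g)
        if len(idx) < 1:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    a = len(groups)
    if n - a == 0 or ss_within == 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a dissimilarity matrix.

    The pseudo-F statistic compares among- to within-group sums of squared
    dissimilarities; its null distribution is built by permuting the group
    labels.  p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so p is never 0.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    labels = np.asarray(list(groups))
    if len(labels) != d.shape[0]:
        raise ValueError("group labels must match matrix dimension")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    d2 = d * d
    f_obs = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm = _pseudo_f(d2, rng.permutation(labels))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(
        pseudo_f=float(f_obs),
        p=float(p),
        n_perm=n_perm,
        n_groups=len(np.unique(labels)),
        n_samples=d.shape[0],
    )
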