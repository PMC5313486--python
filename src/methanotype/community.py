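"""Rumen community structure: OTU-table processing and distance-based stats.

Implements the filtering chain applied to triplicate 16S OTU libraries
(replicate-consistency filter, fractional read-count threshold, even-depth
rarefaction), relative-abundance aggregation by taxonomic rank, Bray-Curtis
dissimilarity, principal coordinate analysis, distance-based non-parametric
MANOVA (PERMANOVA) with optional whole-cow restricted permutations,
FDR-controlled differential OTU abundance between community clusters, and
archaeal clade ratios (M. gottschalkii : M. ruminantium).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from ._rng import child_rng

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "OrdinationResult",
    "PermanovaResult",
    "filter_replicate_consistency",
    "filter_min_reads",
    "min_reads_threshold",
    "subsample_even_depth",
    "relative_abundance",
    "bray_curtis",
    "pcoa",
    "permanova",
    "differential_otus",
    "clade_ratio",
]

_RANK_PREFIX = {
    "kingdom": "k__",
    "domain": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
}


@dataclasses.dataclass
class OtuTable:
    """OTU x library count matrix with replicate structure and taxonomy.

    ``counts``: non-negative integer matrix, rows = OTU ids, columns =
    library ids.  ``samples``: per-library metadata (cow_id, period,
    replicate).  ``taxonomy``: per-OTU lineage string, domain flag
    (bacteria/archaea) and, for archaeal OTUs, a clade label.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    taxonomy: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if vals.size and (np.any(vals < 0) or not np.issubdtype(vals.dtype, np.integer)):
            if not np.allclose(vals, np.round(vals)) or np.any(vals < 0):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(np.int64)
        if set(self.counts.columns) != set(self.samples.index):
            raise ValueError("every library must map to exactly one metadata row")
        missing_tax = set(self.counts.index) - set(self.taxonomy.index)
        if missing_tax:
            raise ValueError(f"taxonomy missing for OTUs: {sorted(missing_tax)[:5]} ...")

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_libraries(self) -> int:
        return self.counts.shape[1]

    def replicate_groups(self):
        """Iterate (cow, period) -> list of library ids."""
        return self.samples.groupby(["cow_id", "period"], sort=True).groups.items()

    def _with_counts(self, counts: pd.DataFrame) -> "OtuTable":
        return OtuTable(
            counts=counts,
            samples=self.samples.loc[list(counts.columns)].copy(),
            taxonomy=self.taxonomy.loc[counts.index].copy(),
        )


def filter_replicate_consistency(
    table: OtuTable, mode: str = "any-sample", n_replicates: int = 3
) -> OtuTable:
    """Retain OTUs observed in all replicate libraries of a sample.

    A sample is one (cow, period) with exactly ``n_replicates`` libraries.
    Under ``mode='any-sample'`` (default) an OTU is kept if all replicates of
    at least one sample contain it; ``mode='every-sample'`` requires every
    sample's replicates to contain it (a far stricter reading).
    """
    if mode not in ("any-sample", "every-sample"):
        raise ValueError(f"unknown mode {mode!r}")
    present = table.counts > 0
    sample_ok = []
    for (cow, period), libs in table.replicate_groups():
        if len(libs) != n_replicates:
            raise ValueError(
                f"sample ({cow}, {period}) has {len(libs)} replicates, expected {n_replicates}"
            )
        sample_ok.append(present[list(libs)].all(axis=1))
    if not sample_ok:
        return table._with_counts(table.counts.copy())
    ok = pd.concat(sample_ok, axis=1)
    keep = ok.any(axis=1) if mode == "any-sample" else ok.all(axis=1)
    dropped = table.counts.index[~keep]
    if len(dropped):
        logger.info(
            "replicate-consistency filter removed %d OTUs (%s)", len(dropped), mode
        )
    return table._with_counts(table.counts.loc[keep])


def min_reads_threshold(total_reads: int, fraction: float) -> int:
    """Read-count threshold: floor(fraction x grand total of reads)."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return math.floor(fraction * total_reads)


def filter_min_reads(table: OtuTable, fraction: float) -> OtuTable:
    """Drop OTUs whose total read count is at or below a fractional threshold.

    The threshold is floor(fraction x grand total); an OTU is retained only
    if its total exceeds it (strictly more reads than the threshold).
    """
    threshold = min_reads_threshold(int(table.counts.to_numpy().sum()), fraction)
    totals = table.counts.sum(axis=1)
    keep = totals > threshold
    logger.info(
        "min-reads filter at fraction %g (threshold %d reads) removed %d of %d OTUs",
        fraction,
        threshold,
        int((~keep).sum()),
        table.n_otus,
    )
    return table._with_counts(table.counts.loc[keep])


def subsample_even_depth(
    table: OtuTable, depth: int | None = None, seed: int = 0
) -> OtuTable:
    """Rarefy every library to the same depth without replacement.

    ``depth`` defaults to the smallest library total.  A library whose total
    is below an explicit depth is dropped with a logged warning.  Each
    library uses its own child stream of ``seed``, so dropping one library
    never changes the rarefaction of the others.
    """
    totals = table.counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    keep_cols = []
    new_cols = {}
    for lib in table.counts.columns:
        total = int(totals[lib])
        if total < depth:
            logger.warning(
                "library %s dropped: %d reads below rarefaction depth %d",
                lib,
                total,
                depth,
            )
            continue
        col = table.counts[lib].to_numpy(dtype=np.int64)
        if total == depth:
            new_cols[lib] = col
        else:
            rng = child_rng(seed, "rarefy", lib)
            new_cols[lib] = rng.multivariate_hypergeometric(col, depth)
        keep_cols.append(lib)
    counts = pd.DataFrame(new_cols, index=table.counts.index, columns=keep_cols)
    return table._with_counts(counts)


def _rank_label(lineage: str, rank: str) -> str:
    prefix = _RANK_PREFIX[rank]
    parts = [p.strip() for p in lineage.split(";")]
    upto = []
    for p in parts:
        upto.append(p)
        if p.startswith(prefix):
            return "; ".join(upto)
    return "; ".join(upto) + f"; {prefix}unclassified"


def relative_abundance(
    table: OtuTable, level: str = "otu", domain: str | None = None
) -> pd.DataFrame:
    """Pool replicates, aggregate to a taxonomic rank and normalise rows.

    Replicate libraries of each (cow, period) sample are summed, counts are
    aggregated to ``level`` ('otu', 'genus', 'family', ..., 'domain'), and
    each sample row is divided by its total so rows sum to 1.  With
    ``domain='archaea'`` (or 'bacteria') only that domain's OTUs enter and
    rows are normalised within the domain, e.g. "% of archaea sequences".
    """
    if level != "otu" and level not in _RANK_PREFIX:
        raise ValueError(f"unknown rank {level!r}")
    counts = table.counts
    tax = table.taxonomy
    if domain is not None:
        keep = tax["domain"] == domain
        counts = counts.loc[keep[keep].index.intersection(counts.index)]
        tax = tax.loc[counts.index]

    pooled = {}
    for (cow, period), libs in table.replicate_groups():
        pooled[(cow, period)] = counts[list(libs)].sum(axis=1)
    mat = pd.DataFrame(pooled).T  # samples x OTUs
    mat.index = pd.MultiIndex.from_tuples(mat.index, names=["cow_id", "period"])

    if level != "otu":
        labels = tax["lineage"].map(lambda s: _rank_label(s, level))
        mat = mat.T.groupby(labels.loc[mat.columns]).sum().T
    row_sums = mat.sum(axis=1)
    return mat.div(row_sums.replace(0, np.nan), axis=0)


def bray_curtis(abund: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample rows.

    D_ij = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk); symmetric with zero
    diagonal and entries in [0, 1] for non-negative data.
    """
    x = abund.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise ValueError("at least 2 samples are required")
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    zero_rows = np.where(x.sum(axis=1) == 0)[0]
    if len(zero_rows) >= 2:
        raise ValueError("Bray-Curtis is undefined between two all-zero samples")
    d = squareform(pdist(x, metric="braycurtis"))
    ids = ["|".join(str(k) for k in key) if isinstance(key, tuple) else str(key)
           for key in abund.index]
    return DistanceMatrix(d, ids=ids)


@dataclasses.dataclass
class OrdinationResult:
    """PCoA embedding: coordinates, explained variance and full spectrum.

    ``explained_pct`` is computed over the positive eigenvalues only;
    negative eigenvalues (non-Euclidean distances) are reported in
    ``eigenvalues`` but their axes are dropped.
    """

    coordinates: pd.DataFrame  # samples x PCo axes
    explained_pct: np.ndarray
    eigenvalues: np.ndarray


def pcoa(dm: DistanceMatrix | np.ndarray, ids=None) -> OrdinationResult:
    """Principal coordinate analysis by Gower double-centering.

    B = -1/2 * J D^2 J with J the centering operator; coordinates are the
    eigenvectors of B scaled by the square root of their (positive)
    eigenvalues.
    """
    if isinstance(dm, DistanceMatrix):
        d = dm.data
        ids = list(dm.ids)
    else:
        d = np.asarray(dm, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
            raise ValueError("distance matrix must be square and symmetric")
        if ids is None:
            ids = [str(i) for i in range(d.shape[0])]
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = max(abs(eigvals[0]), 1.0) * 1e-10
    pos = eigvals > tol
    n_neg = int((eigvals < -tol).sum())
    if n_neg:
        logger.info(
            "pcoa: %d negative eigenvalues (largest magnitude %.3g) dropped",
            n_neg,
            float(-eigvals.min()),
        )
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    explained = eigvals[pos] / eigvals[pos].sum() * 100.0
    columns = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=columns),
        explained_pct=explained,
        eigenvalues=eigvals,
    )


@dataclasses.dataclass(frozen=True)
class PermanovaResult:
    statistic: float  # pseudo-F
    p_value: float
    n_permutations: int


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
    permute_unit=None,
) -> PermanovaResult:
    """Distance-based non-parametric MANOVA (pseudo-F permutation test).

    The pseudo-F statistic contrasts among- against within-group sums of
    squared distances.  The p-value is (1 + #{permuted F >= observed F}) /
    (1 + n_permutations).  With ``permute_unit`` (e.g. a cow id per sample),
    permutations shuffle group labels between whole units so repeated
    measures of one cow move together.
    """
    if n_permutations < 99:
        raise ValueError("at least 99 permutations are required")
    labels = np.asarray(pd.Series(grouping).reindex(dm.ids).to_numpy()
                        if isinstance(grouping, (pd.Series, dict, Mapping))
                        else list(grouping))
    if pd.isna(labels).any():
        raise ValueError("grouping must cover every sample in the distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("at least 2 groups are required")
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")

    d2 = dm.data**2
    n = len(labels)
    a = len(uniq)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n

    def pseudo_f(lab: np.ndarray) -> float:
        ss_within = 0.0
        for g in uniq:
            idx = np.where(lab == g)[0]
            ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
        ss_among = ss_total - ss_within
        if ss_within <= 0:
            return np.inf
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(labels)
    rng = child_rng(seed, "permanova")

    if permute_unit is not None:
        units = np.asarray(pd.Series(permute_unit).reindex(dm.ids).to_numpy()
                           if isinstance(permute_unit, (pd.Series, dict, Mapping))
                           else list(permute_unit))
        uniq_units, unit_idx = np.unique(units, return_inverse=True)
        unit_labels = np.empty(len(uniq_units), dtype=labels.dtype)
        for i, u in enumerate(uniq_units):
            lab_u = np.unique(labels[units == u])
            if len(lab_u) != 1:
                raise ValueError(f"unit {u!r} spans multiple groups; cannot permute by unit")
            unit_labels[i] = lab_u[0]

        def permuted() -> np.ndarray:
            return rng.permutation(unit_labels)[unit_idx]

    else:

        def permuted() -> np.ndarray:
            return rng.permutation(labels)

    exceed = 0
    for _ in range(n_permutations):
        if pseudo_f(permuted()) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(statistic=float(f_obs), p_value=float(p),
                           n_permutations=n_permutations)


def differential_otus(
    rel: pd.DataFrame,
    clusters: pd.Series,
    min_fraction: float = 0.001,
    taxonomy: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Differential OTU abundance between community clusters L and H.

    ``rel`` holds per-(cow, period) relative abundances (rows indexed by a
    (cow_id, period) MultiIndex, columns = OTU ids); ``clusters`` maps each
    cow to 'L' or 'H'.  OTUs whose mean relative abundance is at or below
    ``min_fraction`` are excluded before testing.  Periods are averaged to
    one value per cow (removing the repeated-measures dependence), the two
    clusters are compared with Welch's t on logit-transformed proportions
    (half-minimum pseudo-proportion), and p-values are Benjamini-Hochberg
    adjusted over exactly the tested set.

    Rows are sorted by cluster of enrichment (L first) then mean abundance.
    """
    clusters = pd.Series(clusters)
    counts = clusters.value_counts()
    if (counts < 2).any() or len(counts) < 2:
        raise ValueError("each cluster needs at least 2 cows")

    keep = rel.columns[rel.mean(axis=0) > min_fraction]
    tested = rel[keep]
    cow_means = tested.groupby(level="cow_id").mean()
    cow_means = cow_means.loc[cow_means.index.intersection(clusters.index)]
    grp = clusters.loc[cow_means.index]

    pos = tested.to_numpy()
    pos = pos[pos > 0]
    pseudo = pos.min() / 2.0 if len(pos) else 1e-6

    def logit(p):
        q = np.clip(p + pseudo, 1e-12, 1 - 1e-12)
        return np.log(q / (1 - q))

    rows = []
    xl = cow_means[grp == "L"]
    xh = cow_means[grp == "H"]
    for otu in keep:
        a, b = xl[otu].to_numpy(), xh[otu].to_numpy()
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            t_stat, p_val = 0.0, 1.0
        else:
            t_stat, p_val = stats.ttest_ind(logit(a), logit(b), equal_var=False)
        sed = float(np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b)) * 100.0)
        rows.append(
            {
                "otu_id": otu,
                "taxonomy": (taxonomy["lineage"].get(otu, "") if taxonomy is not None else ""),
                "mean_L": float(a.mean() * 100.0),
                "mean_H": float(b.mean() * 100.0),
                "sed": sed,
                "statistic": float(t_stat),
                "p": float(p_val),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["enriched_in"] = np.where(out["mean_L"] >= out["mean_H"], "L", "H")
        out = out.sort_values(
            by=["enriched_in", "mean_L", "mean_H"], ascending=[True, False, False]
        ).reset_index(drop=True)
    else:
        out["q"] = []
        out["enriched_in"] = []
    return out


def clade_ratio(
    archaeal_rel: pd.DataFrame,
    groups: pd.Series | None = None,
    gottschalkii_col: str = "gottschalkii",
    ruminantium_col: str = "ruminantium",
) -> tuple[pd.Series, pd.Series | None]:
    """Per-sample and per-group M. gottschalkii : M. ruminantium ratio.

    ``archaeal_rel`` holds per-sample clade shares (columns include the two
    clades).  A zero ruminantium share yields an infinite ratio, flagged via
    a logged warning.  ``groups`` (e.g. emitter group per sample) triggers
    per-group mean ratios.
    """
    for col in (gottschalkii_col, ruminantium_col):
        if col not in archaeal_rel.columns:
            raise ValueError(f"clade column {col!r} missing")
    rum = archaeal_rel[ruminantium_col]
    got = archaeal_rel[gottschalkii_col]
    if (rum == 0).any():
        logger.warning(
            "%d samples have zero ruminantium-clade share; ratio is infinite",
            int((rum == 0).sum()),
        )
    with np.errstate(divide="ignore"):
        per_sample = got / rum
    per_sample.name = "gottschalkii_to_ruminantium"
    per_group = None
    if groups is not None:
        groups = pd.Series(groups)
        aligned = groups.reindex(per_sample.index)
        per_group = per_sample.groupby(aligned).mean()
    return per_sample, per_group
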