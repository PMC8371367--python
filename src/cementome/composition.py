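"""Amino-acid composition profiling, enrichment-group clustering and PCA.

Bulk cement proteins are conventionally classified by amino-acid bias —
glycine/alanine/serine/threonine-rich (GrCP), leucine-rich (LrCP) and
cysteine-rich (CrCP) groups.  This module computes per-protein composition
vectors, clusters them hierarchically, labels each cluster by which
residues its mean composition enriches over the proteome background, and
runs PCA with per-residue contribution scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from cementome.align import SimilarityTable
from cementome.seqio import AMINO_ACIDS, SequenceRecord

#: residues defining each enrichment base label
GROUP_RESIDUES = {"LrCP": {"L"}, "GrCP": {"G", "A", "S", "T"}, "CrCP": {"C"}}


@dataclass(frozen=True)
class CompositionProfile:
    """20-dimensional amino-acid percentage vector for one protein.

    Percentages are over canonical residues only (X is excluded from both
    numerator and denominator) and sum to 100.
    """

    accession: str
    percentages: tuple[float, ...]  # ordered as seqio.AMINO_ACIDS

    def as_dict(self) -> dict[str, float]:
        return dict(zip(AMINO_ACIDS, self.percentages))


@dataclass(frozen=True)
class GroupLabel:
    """Enrichment label for one cluster, e.g. GrCP1 or LrCP2.

    ``minor`` marks clusters with no residue above the enrichment margin;
    such clusters are sub-labelled by their top residue in
    ``defining_residues``.
    """

    value: str
    defining_residues: frozenset[str]


def aa_composition(record: SequenceRecord) -> CompositionProfile:
    """Percentage of each canonical residue over the canonical-residue count."""
    if record.alphabet != "protein":
        raise ValueError("composition is defined for protein sequences")
    counts = {aa: 0 for aa in AMINO_ACIDS}
    for ch in record.sequence:
        if ch in counts:
            counts[ch] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"sequence {record.id!r} contains no canonical residues")
    return CompositionProfile(
        accession=record.id,
        percentages=tuple(100.0 * counts[aa] / total for aa in AMINO_ACIDS),
    )


def profiles_to_matrix(profiles: list[CompositionProfile]) -> pd.DataFrame:
    """Profiles as a (protein x residue) DataFrame, rows sorted by accession."""
    df = pd.DataFrame(
        [p.percentages for p in profiles],
        index=[p.accession for p in profiles],
        columns=list(AMINO_ACIDS),
    )
    return df.sort_index()


def cluster_compositions(
    profiles: list[CompositionProfile],
    k: int,
    scaling: str = "zscore_by_residue",
) -> tuple[dict[str, int], np.ndarray, list[str]]:
    """Agglomerative clustering of composition profiles into ``k`` clusters.

    Complete linkage on Euclidean distances, computed on the residue-wise
    z-scored matrix by default (``scaling="none"`` clusters raw
    percentages).  Returns ``(assignments, linkage, accessions)`` where
    assignments map accession -> cluster id (1..k); the dendrogram is the
    scipy linkage matrix over the sorted accession list, so the result is
    independent of input order.  Ties on identical profiles are resolved by
    scipy's deterministic merge order.
    """
    if k < 2:
        raise ValueError("cluster count k must be >= 2")
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} profiles, got {len(profiles)}")
    matrix = profiles_to_matrix(profiles)
    data = matrix.to_numpy(dtype=float)
    if scaling == "zscore_by_residue":
        mu = data.mean(axis=0)
        sd = data.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        data = (data - mu) / sd
    elif scaling != "none":
        raise ValueError(f"unknown scaling {scaling!r}")
    linkage = hierarchy.linkage(pdist(data, metric="euclidean"), method="complete")
    flat = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    return dict(zip(matrix.index, (int(c) for c in flat))), linkage, list(matrix.index)


def label_enrichment_groups(
    clusters: dict[str, int],
    profiles: list[CompositionProfile],
    margin: float = 1.5,
    background: tuple[pd.Series, pd.Series] | None = None,
    min_excess_pp: float = 2.0,
) -> dict[int, GroupLabel]:
    """Label each cluster by the residues it enriches over the background.

    A cluster enriches residue r when its mean percentage exceeds
    ``background_mean + margin * SD`` and the absolute excess is at least
    ``min_excess_pp`` percentage points (guarding against compositional
    closure: a cluster compared against a heavily biased background looks
    mildly "enriched" in every other residue).  ``background`` may supply explicit
    per-residue (mean, SD) series; by default the background mean is the
    leave-cluster-out mean (so a large enriched group is not its own
    reference) and the SD is the pooled within-cluster SD (an ANOVA-style
    noise estimate that is not inflated by between-class spread).  The base
    label is CrCP if C is enriched, else LrCP/GrCP by whichever of L or
    G/A/S/T dominates the enrichment excess; clusters with no enriched
    residue are ``minor`` (sub-labelled by their top residue).  Multiple
    clusters sharing a base label are numbered 1, 2, ... by descending mean
    enrichment of their defining residues.
    """
    matrix = profiles_to_matrix(profiles)
    pooled_sd = _pooled_within_cluster_sd(matrix, clusters)
    raw: dict[int, tuple[str, frozenset[str], float]] = {}
    for cid in sorted(set(clusters.values())):
        members = [acc for acc, c in clusters.items() if c == cid]
        if background is not None:
            bg_mean, bg_sd = background
        else:
            rest = matrix.drop(index=members)
            if len(rest) == 0:
                rest = matrix
            bg_mean = rest.mean(axis=0)
            bg_sd = pooled_sd
        cmean = matrix.loc[members].mean(axis=0)
        excess = (cmean - bg_mean) / bg_sd.replace(0, np.nan)
        enriched = frozenset(
            aa for aa in AMINO_ACIDS
            if cmean[aa] > bg_mean[aa] + margin * bg_sd[aa]
            and cmean[aa] - bg_mean[aa] >= min_excess_pp
        )
        if not enriched:
            top = str(excess.fillna(-np.inf).idxmax())
            raw[cid] = ("minor", frozenset({top}), float(excess.fillna(0).max()))
            continue
        if "C" in enriched:
            base = "CrCP"
        else:
            score = {
                "LrCP": sum(float(excess.get(aa, 0) or 0) for aa in GROUP_RESIDUES["LrCP"] & enriched),
                "GrCP": sum(float(excess.get(aa, 0) or 0) for aa in GROUP_RESIDUES["GrCP"] & enriched),
            }
            base = max(score, key=lambda b: (score[b], b)) if any(score.values()) else "minor"
        defining = frozenset(GROUP_RESIDUES.get(base, set()) & enriched) or enriched
        strength = float(cmean[list(defining)].mean())
        raw[cid] = (base, defining, strength)
    labels: dict[int, GroupLabel] = {}
    for base in sorted({b for b, _, _ in raw.values()}):
        cids = sorted((cid for cid, (b, _, _) in raw.items() if b == base),
                      key=lambda cid: (-raw[cid][2], cid))
        multiple = len(cids) > 1 and base != "minor"
        for rank, cid in enumerate(cids, start=1):
            name = f"{base}{rank}" if multiple else base
            labels[cid] = GroupLabel(value=name, defining_residues=raw[cid][1])
    return labels


def _pooled_within_cluster_sd(matrix: pd.DataFrame, clusters: dict[str, int]) -> pd.Series:
    """Per-residue pooled SD around cluster means (global SD when degenerate)."""
    sq = pd.Series(0.0, index=matrix.columns)
    dof = 0
    for cid in set(clusters.values()):
        members = [acc for acc, c in clusters.items() if c == cid]
        if len(members) < 2:
            continue
        dev = matrix.loc[members] - matrix.loc[members].mean(axis=0)
        sq += (dev**2).sum(axis=0)
        dof += len(members) - 1
    if dof == 0:
        return matrix.std(axis=0, ddof=0)
    return np.sqrt(sq / dof)


@dataclass
class PCAResult:
    """PCA of the composition matrix with per-residue contributions.

    ``contributions[j, pc] = 100 * loading(j, pc)^2 / sum_j loading(j, pc)^2``
    — the share of each amino acid in each component, summing to 100 per PC.
    """

    scores: pd.DataFrame          # proteins x PCs
    loadings: pd.DataFrame        # residues x PCs
    variance_explained: np.ndarray
    contributions: pd.DataFrame   # residues x PCs, percent
    mean: np.ndarray


def pca_composition(profiles: list[CompositionProfile], n_components: int = 2) -> PCAResult:
    """PCA on the centered composition matrix (no unit scaling).

    Identical profiles carry zero variance and are a hard error.  The
    decomposition satisfies ``scores @ loadings.T + mean == data``.
    """
    if len(profiles) < 3:
        raise ValueError("PCA needs at least 3 profiles")
    matrix = profiles_to_matrix(profiles)
    if n_components > min(matrix.shape):
        raise ValueError("more components requested than profiles/variables")
    data = matrix.to_numpy(dtype=float)
    mean = data.mean(axis=0)
    centered = data - mean
    if np.allclose(centered, 0):
        raise ValueError("all composition profiles are identical: zero variance")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention: largest-magnitude loading positive, for determinism
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    var = (s**2) / (len(profiles) - 1)
    frac = var / matrix.to_numpy().var(axis=0, ddof=1).sum()
    pcs = [f"PC{i+1}" for i in range(n_components)]
    loadings = pd.DataFrame(vt[:n_components].T, index=list(AMINO_ACIDS), columns=pcs)
    scores = pd.DataFrame(u[:, :n_components] * s[:n_components], index=matrix.index, columns=pcs)
    contrib = 100.0 * loadings**2 / (loadings**2).sum(axis=0)
    return PCAResult(
        scores=scores,
        loadings=loadings,
        variance_explained=frac[:n_components],
        contributions=contrib,
        mean=mean,
    )


def group_overlap_venn(
    labels_a: dict[str, str],
    labels_b: dict[str, str],
    cross: SimilarityTable,
) -> pd.DataFrame:
    """Per-group cross-species overlap with asymmetric member counts.

    ``labels_a``/``labels_b`` map accession -> group label per species.  For
    every observed (group_A, group_B) pair the table reports how many
    proteins of each side participate in at least one cross-species match
    within that pair; same-group rows are the classical Venn overlap, rows
    with differing labels expose homologues that fall in different
    composition groups.  Per-group totals and unmatched counts are included
    for the same-group rows.
    """
    pair_members_a: dict[tuple[str, str], set[str]] = {}
    pair_members_b: dict[tuple[str, str], set[str]] = {}
    for row in cross:
        ga = labels_a.get(row.query_id)
        gb = labels_b.get(row.subject_id)
        if ga is None or gb is None:
            continue
        pair_members_a.setdefault((ga, gb), set()).add(row.query_id)
        pair_members_b.setdefault((ga, gb), set()).add(row.subject_id)
    totals_a = pd.Series(list(labels_a.values())).value_counts()
    totals_b = pd.Series(list(labels_b.values())).value_counts()
    pairs = sorted(set(pair_members_a) | {(g, g) for g in set(labels_a.values()) & set(labels_b.values())})
    rows = []
    for ga, gb in pairs:
        ma = pair_members_a.get((ga, gb), set())
        mb = pair_members_b.get((ga, gb), set())
        rows.append(
            {
                "group_A": ga,
                "group_B": gb,
                "same_group": ga == gb,
                "matched_A": len(ma),
                "matched_B": len(mb),
                "total_A": int(totals_a.get(ga, 0)) if ga == gb else pd.NA,
                "total_B": int(totals_b.get(gb, 0)) if ga == gb else pd.NA,
            }
        )
    return pd.DataFrame(rows, columns=["group_A", "group_B", "same_group",
                                       "matched_A", "matched_B", "total_A", "total_B"])
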