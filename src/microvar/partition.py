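"""Partitioning pairwise dissimilarities into variation sources.

Each within-modality sample pair is assigned to exactly one of five
categories — or to none, when more than one design variable separates the
pair, so that every category isolates a single source of variation:

* LIBPREP     same subject, day and extraction, different library prep
              (technical: library prep / sequencing run);
* EXTRACTION  same subject, day and library-prep index, different extraction
              (technical: DNA extraction);
* DAILY       same subject, consecutive days within a week (gap of 1);
* WEEKLY      same subject, days exactly one week apart (gap of 7);
* SUBJECT     different subjects.

This module also quantifies cross-modality agreement: genus-level
concordance between matched amplicon and shotgun profiles (absent genera
counted as zeroes), lineage matching (exact vs nested), abundance-weighted
taxonomic-resolution summaries, and top-taxa extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from skbio import DistanceMatrix

from .lineage import GENUS_DEPTH, RANKS, Lineage
from .synth import SampleMeta

CATEGORIES = ("LIBPREP", "EXTRACTION", "DAILY", "WEEKLY", "SUBJECT")
TECHNICAL_CATEGORIES = ("LIBPREP", "EXTRACTION")


class PartitionError(ValueError):
    pass


# --------------------------------------------------------------------------
# pair classification
# --------------------------------------------------------------------------

def classify_pair(meta_a: SampleMeta, meta_b: SampleMeta) -> str | None:
    """Variation category of one sample pair, or None if no single source
    of variation separates the two samples."""
    if meta_a.modality is not meta_b.modality:
        raise PartitionError(
            f"cannot classify a mixed-modality pair: {meta_a.sample_id} vs {meta_b.sample_id}"
        )
    if meta_a.subject != meta_b.subject:
        return "SUBJECT"
    if meta_a.day == meta_b.day:
        same_ext = meta_a.extraction_rep == meta_b.extraction_rep
        same_lib = meta_a.libprep_rep == meta_b.libprep_rep
        if same_ext and not same_lib:
            return "LIBPREP"
        if same_lib and not same_ext:
            return "EXTRACTION"
        return None  # identical pair is never passed; both-differ is excluded
    gap = abs(meta_a.day - meta_b.day)
    if gap == 1 and meta_a.week == meta_b.week:
        return "DAILY"
    if gap == 7:
        return "WEEKLY"
    return None


def partition_dissimilarities(
    D: DistanceMatrix, metadata: dict[str, SampleMeta] | list[SampleMeta]
) -> pd.DataFrame:
    """One VariationRecord per classifiable unordered sample pair.

    Returns a tidy frame with columns sample_a, sample_b, modality, category
    and dissimilarity, ready for the group tests and boxplot exports.
    """
    if isinstance(metadata, list):
        metadata = {m.sample_id: m for m in metadata}
    missing = [sid for sid in D.ids if sid not in metadata]
    if missing:
        raise PartitionError(f"samples missing from metadata: {missing[:5]}")
    modalities = {metadata[sid].modality for sid in D.ids}
    if len(modalities) > 1:
        raise PartitionError("distance matrix mixes modalities; partition one at a time")

    ids = list(D.ids)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = metadata[ids[i]], metadata[ids[j]]
            cat = classify_pair(a, b)
            if cat is None:
                continue
            rows.append(
                (ids[i], ids[j], a.modality.value, cat, float(D[ids[i], ids[j]]))
            )
    return pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "modality", "category", "dissimilarity"]
    )


def category_counts(records: pd.DataFrame) -> dict[str, int]:
    """Pairs per category, with zeros for absent categories."""
    counts = records["category"].value_counts().to_dict() if len(records) else {}
    return {cat: int(counts.get(cat, 0)) for cat in CATEGORIES}


# --------------------------------------------------------------------------
# lineage matching and concordance
# --------------------------------------------------------------------------

def match_lineages(a: Lineage | str, b: Lineage | str) -> str:
    """'exact' for identical lineages, 'nested' when one is a strict
    rank-prefix of the other, else 'none'."""
    la = a if isinstance(a, Lineage) else Lineage.parse(str(a))
    lb = b if isinstance(b, Lineage) else Lineage.parse(str(b))
    if la.names == lb.names:
        return "exact"
    if la.is_prefix_of(lb) or lb.is_prefix_of(la):
        return "nested"
    return "none"


def collapse_to_genus(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a lineage-indexed table to genus level.

    Features lacking a genus rank are excluded; features resolved deeper
    than genus are truncated to their genus prefix and summed.
    """
    keys = {}
    for feat in table.index:
        lin = Lineage.parse(str(feat))
        if lin.depth >= GENUS_DEPTH:
            keys[feat] = str(lin.truncate(GENUS_DEPTH))
    sub = table.loc[list(keys)]
    grouped = sub.groupby(sub.index.map(keys), sort=True).sum()
    grouped.index.name = "genus"
    return grouped


def genus_concordance(
    table_amplicon: pd.DataFrame,
    table_shotgun: pd.DataFrame,
    metadata: dict[str, SampleMeta] | list[SampleMeta],
    per_sample: bool = False,
) -> tuple[float, float, int]:
    """Pearson r and Spearman rho between matched genus-level profiles.

    Samples are matched 1:1 across modalities by their design coordinates
    (subject, day, extraction, libprep).  Both tables are collapsed to
    genus; the union of genera is used, absent genera scoring zero.  The
    default pools all (matched sample x genus) cells into one pair of
    vectors; ``per_sample=True`` instead averages per-sample correlations.

    Returns ``(pearson_r, spearman_rho, n_cells)``.
    """
    if isinstance(metadata, list):
        metadata = {m.sample_id: m for m in metadata}

    def unit_map(cols) -> dict[str, str]:
        out = {}
        for sid in cols:
            if sid not in metadata:
                raise PartitionError(f"sample {sid!r} missing from metadata")
            out[metadata[sid].unit_id] = sid
        return out

    units_a = unit_map(table_amplicon.columns)
    units_s = unit_map(table_shotgun.columns)
    shared = sorted(set(units_a) & set(units_s))
    unmatched = set(units_a) ^ set(units_s)
    if unmatched:
        raise PartitionError(f"unmatched samples across modalities: {sorted(unmatched)[:5]}")
    if not shared:
        raise PartitionError("no matched samples")

    ga = collapse_to_genus(table_amplicon)
    gs = collapse_to_genus(table_shotgun)
    genera = sorted(set(ga.index) | set(gs.index))
    ga = ga.reindex(genera, fill_value=0.0)[[units_a[u] for u in shared]]
    gs = gs.reindex(genera, fill_value=0.0)[[units_s[u] for u in shared]]

    if per_sample:
        rs, rhos = [], []
        for u in shared:
            x, y = ga[units_a[u]].to_numpy(), gs[units_s[u]].to_numpy()
            rs.append(sps.pearsonr(x, y).statistic)
            rhos.append(sps.spearmanr(x, y).statistic)
        return float(np.mean(rs)), float(np.mean(rhos)), len(genera) * len(shared)

    x = ga.to_numpy().ravel()
    y = gs.to_numpy().ravel()
    r = float(sps.pearsonr(x, y).statistic)
    rho = float(sps.spearmanr(x, y).statistic)
    return r, rho, int(x.size)


# --------------------------------------------------------------------------
# resolution and top taxa
# --------------------------------------------------------------------------

def resolution_summary(taxa_table: pd.DataFrame) -> dict[str, float]:
    """Abundance-weighted fraction assigned at each rank or deeper.

    Features are lineage strings; weights are feature totals summed over
    samples.  The result maps rank name -> fraction and is monotone
    nonincreasing with rank depth.
    """
    if taxa_table.empty:
        raise PartitionError("empty taxa table")
    weights = taxa_table.sum(axis=1).to_numpy(dtype=float)
    total = weights.sum()
    if total <= 0:
        raise PartitionError("taxa table has zero total abundance")
    depths = np.array([Lineage.parse(str(f)).depth for f in taxa_table.index])
    return {
        rank: float(weights[depths >= d + 1].sum() / total)
        for d, rank in enumerate(RANKS)
    }


def top_taxa(table: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """The n features with the highest mean relative abundance.

    Sorted descending; ties broken by lexicographic feature id.  Returns a
    frame with a ``mean_abundance`` column indexed by feature.
    """
    means = table.mean(axis=1)
    order = sorted(means.index, key=lambda f: (-means[f], str(f)))
    out = means.loc[order[: min(n, len(order))]].to_frame("mean_abundance")
    out.index.name = table.index.name or "feature"
    return out
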