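"""Post-alignment profiling: hit tables -> filtered relative-abundance tables.

Implements the shotgun annotation rules:

* ties among equally good reference hits are broken "capitalistically", i.e.
  so as to minimize the number of distinct OTUs invoked (greedy hitting-set
  heuristic; exact minimization is NP-hard);
* each read's taxonomy is the lowest common ancestor consistent across at
  least 80% of its tied reference genomes (inclusive threshold);
* OTU counts are normalized to the average genome length of the OTUs
  detected in the sample;
* OTUs below one millionth of all assigned counts, OTUs with < 0.01% of
  their unique genome regions covered AND < 1% of the whole genome covered,
  and samples with fewer than 10,000 mapped reads are discarded;
* KO functional counts come straight from gene-level hits and collapse to
  enzymes (a KO mapping to k enzymes contributes its full count to each).

The amplicon path only needs one step here: ASVs sharing an identical
taxonomic assignment are collapsed into a single taxa-table feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import READ_LENGTH
from .lineage import Lineage
from .synth import ReferenceDB

DEFAULT_LCA_THRESHOLD = 0.8
DEFAULT_MIN_FRAC = 1e-6
DEFAULT_MIN_UNIQUE_COV = 1e-4
DEFAULT_MIN_GENOME_COV = 1e-2
DEFAULT_MIN_SAMPLE_DEPTH = 10_000


class ProfilerError(ValueError):
    pass


def _tie_sets(hits: pd.DataFrame) -> pd.Series:
    """Column of frozensets from the ';'-joined tied_genome_ids column."""
    def parse(s) -> frozenset[str]:
        if isinstance(s, frozenset):
            return s
        ids = frozenset(x for x in str(s).split(";") if x)
        if not ids:
            raise ProfilerError("empty tie set in hit table")
        return ids
    return hits["tied_genome_ids"].map(parse)


# --------------------------------------------------------------------------
# capitalist tie resolution
# --------------------------------------------------------------------------

def resolve_ties_capitalist(hits: pd.DataFrame) -> pd.DataFrame:
    """Assign each read one genome from its tie set, greedily minimizing the
    number of distinct OTUs used overall.

    Greedy hitting set: repeatedly pick the genome covering the most
    still-unresolved reads (lexicographically smallest id on ties) and give
    it all its reads.  Returns a copy of ``hits`` with a ``chosen_genome``
    column; the original tie sets are kept so lineage assignment can still
    see the full ambiguity.
    """
    if hits.empty:
        out = hits.copy()
        out["chosen_genome"] = pd.Series(dtype=object)
        return out
    sets = _tie_sets(hits)
    # work on unique tie sets weighted by multiplicity
    uniq: dict[frozenset[str], int] = {}
    for s in sets:
        uniq[s] = uniq.get(s, 0) + 1
    unresolved = dict(uniq)
    choice: dict[frozenset[str], str] = {}
    while unresolved:
        cover: dict[str, int] = {}
        for s, w in unresolved.items():
            for g in s:
                cover[g] = cover.get(g, 0) + w
        best = min(cover, key=lambda g: (-cover[g], g))
        for s in [s for s in unresolved if best in s]:
            choice[s] = best
            del unresolved[s]
    out = hits.copy()
    out["chosen_genome"] = sets.map(choice)
    return out


def minimum_otu_count(tie_sets: list[frozenset[str]]) -> int:
    """Exact minimum number of distinct genomes hitting every tie set.

    Exhaustive search over genome subsets — usable only on small inputs;
    this is the oracle the greedy heuristic is checked against.
    """
    from itertools import combinations

    genomes = sorted(set().union(*tie_sets)) if tie_sets else []
    for r in range(0, len(genomes) + 1):
        for subset in combinations(genomes, r):
            chosen = set(subset)
            if all(s & chosen for s in tie_sets):
                return r
    return len(genomes)


# --------------------------------------------------------------------------
# LCA assignment
# --------------------------------------------------------------------------

def assign_lineage(
    tie_set, refdb: ReferenceDB, threshold: float = DEFAULT_LCA_THRESHOLD
) -> Lineage:
    """Deepest lineage prefix shared by >= ``threshold`` of the tie set.

    Walks from the deepest rank upward; at each depth the most common
    lineage prefix is accepted if its support (fraction of tied genomes)
    reaches the threshold, inclusively.  An empty Lineage is returned when
    not even the kingdom reaches consensus.
    """
    ids = sorted(set(tie_set))
    if not ids:
        raise ProfilerError("empty tie set")
    if not 0.0 < threshold <= 1.0:
        raise ProfilerError("threshold must be in (0, 1]")
    lineages = [refdb.lineage_of(g) for g in ids]
    n = len(lineages)
    max_depth = max(lin.depth for lin in lineages)
    for depth in range(max_depth, 0, -1):
        counts: dict[tuple[str, ...], int] = {}
        for lin in lineages:
            if lin.depth >= depth:
                pfx = lin.names[:depth]
                counts[pfx] = counts.get(pfx, 0) + 1
        if not counts:
            continue
        best = min(counts, key=lambda p: (-counts[p], p))
        if counts[best] / n >= threshold:
            return Lineage(best)
    return Lineage(())


# --------------------------------------------------------------------------
# tabulation and coverage
# --------------------------------------------------------------------------

@dataclass
class OtuTable:
    """Genome-level feature table with its side stats.

    ``raw`` holds assigned read counts (genomes x samples); ``coverage``
    holds per-genome covered fractions pooled across all samples;
    ``normalized`` appears after genome-length normalization.
    """

    raw: pd.DataFrame
    lineages: pd.Series
    coverage: pd.DataFrame  # columns: genome_cov, unique_cov
    normalized: pd.DataFrame | None = None

    def copy(self) -> "OtuTable":
        return OtuTable(
            self.raw.copy(), self.lineages.copy(), self.coverage.copy(),
            None if self.normalized is None else self.normalized.copy(),
        )


def _union_length(starts: np.ndarray, length: int) -> tuple[np.ndarray, np.ndarray]:
    """Merged (start, end) segments of fixed-length reads clipped to [0, length)."""
    if starts.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    s = np.sort(np.asarray(starts, dtype=np.int64))
    e = np.minimum(s + READ_LENGTH, length)
    # segment breaks where the next read starts after the running end
    run_end = np.maximum.accumulate(e)
    new_seg = np.empty(s.size, dtype=bool)
    new_seg[0] = True
    new_seg[1:] = s[1:] > run_end[:-1]
    seg_id = np.cumsum(new_seg) - 1
    seg_starts = s[new_seg]
    seg_ends = np.zeros(seg_id.max() + 1, dtype=np.int64)
    np.maximum.at(seg_ends, seg_id, e)
    return seg_starts, seg_ends


def _intersect_length(
    seg_starts: np.ndarray, seg_ends: np.ndarray, intervals
) -> int:
    total = 0
    for a, b in intervals:
        lo = np.maximum(seg_starts, a)
        hi = np.minimum(seg_ends, b)
        total += int(np.maximum(hi - lo, 0).sum())
    return total


def tabulate_assignments(hits: pd.DataFrame, refdb: ReferenceDB) -> OtuTable:
    """Count assigned reads per (genome, sample) and pool coverage per genome.

    Requires a ``chosen_genome`` column (from resolve_ties_capitalist).
    Coverage fractions use the union of read intervals [pos, pos+100)
    against the whole genome and its unique regions, pooled across samples.
    """
    if "chosen_genome" not in hits.columns:
        raise ProfilerError("hits must be tie-resolved first (chosen_genome missing)")
    if hits.empty:
        return OtuTable(
            raw=pd.DataFrame(dtype=int),
            lineages=pd.Series(dtype=object),
            coverage=pd.DataFrame(columns=["genome_cov", "unique_cov"]),
        )
    unknown = set(hits["chosen_genome"]) - set(refdb.genomes)
    if unknown:
        raise ProfilerError(f"genomes not in reference database: {sorted(unknown)}")

    counts = (
        hits.groupby(["chosen_genome", "sample_id"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    counts.index.name = "genome_id"
    counts.columns.name = None

    cov_rows = {}
    for gid, sub in hits.groupby("chosen_genome", sort=True):
        genome = refdb.genomes[gid]
        pos = sub["position"].to_numpy()
        if (pos < 0).any() or (pos + READ_LENGTH > genome.length).any():
            bad = pos[(pos < 0) | (pos + READ_LENGTH > genome.length)][0]
            raise ProfilerError(f"read position {bad} outside genome {gid} (length {genome.length})")
        seg_s, seg_e = _union_length(pos, genome.length)
        covered = int((seg_e - seg_s).sum())
        u_total = sum(b - a for a, b in genome.unique_intervals)
        u_cov = _intersect_length(seg_s, seg_e, genome.unique_intervals)
        cov_rows[gid] = {
            "genome_cov": covered / genome.length,
            "unique_cov": (u_cov / u_total) if u_total else 0.0,
        }
    coverage = pd.DataFrame.from_dict(cov_rows, orient="index").loc[counts.index]
    lineages = pd.Series(
        {gid: str(refdb.lineage_of(gid)) for gid in counts.index}, name="lineage"
    )
    return OtuTable(raw=counts, lineages=lineages, coverage=coverage)


def genome_length_normalize(table: OtuTable, refdb: ReferenceDB) -> OtuTable:
    """Rescale counts to the average genome length of OTUs detected per sample.

    normalized(o, s) = raw(o, s) / length(o) * mean length over OTUs with
    raw(o, s) > 0.  A sample containing a single OTU is left unchanged, and
    a database of equal-length genomes normalizes to the identity.
    """
    out = table.copy()
    if table.raw.empty:
        out.normalized = table.raw.astype(float)
        return out
    lengths = np.array([refdb.genomes[g].length for g in table.raw.index], dtype=float)
    if (lengths <= 0).any():
        raise ProfilerError("zero genome length")
    raw = table.raw.to_numpy(dtype=float)
    detected = raw > 0
    norm = np.zeros_like(raw)
    for j in range(raw.shape[1]):
        d = detected[:, j]
        if not d.any():
            continue
        mean_len = lengths[d].mean()
        norm[:, j] = raw[:, j] / lengths * mean_len
    out.normalized = pd.DataFrame(norm, index=table.raw.index, columns=table.raw.columns)
    return out


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

def apply_filters(
    table: OtuTable,
    refdb: ReferenceDB | None = None,
    min_frac: float = DEFAULT_MIN_FRAC,
    min_unique_cov: float = DEFAULT_MIN_UNIQUE_COV,
    min_genome_cov: float = DEFAULT_MIN_GENOME_COV,
    min_sample_depth: int = DEFAULT_MIN_SAMPLE_DEPTH,
) -> tuple[OtuTable, list[dict]]:
    """Quality filters, applied in a fixed order with a removal log.

    1. samples whose total raw mapped count < ``min_sample_depth``;
    2. OTUs whose pooled raw count is < ``min_frac`` of all assigned counts;
    3. OTUs with unique-region coverage < ``min_unique_cov`` AND whole-genome
       coverage < ``min_genome_cov`` (conjunctive reading: passing either
       coverage check retains the OTU).

    Returns the filtered table and a log with one record per removal.
    """
    log: list[dict] = []
    out = table.copy()
    if out.raw.empty:
        return out, log

    depth = out.raw.sum(axis=0)
    for sid in depth.index[depth < min_sample_depth]:
        log.append({
            "entity": sid, "kind": "sample", "rule": "min_sample_depth",
            "value": int(depth[sid]), "threshold": min_sample_depth,
        })
    keep_samples = depth.index[depth >= min_sample_depth]
    out.raw = out.raw[keep_samples]
    if out.normalized is not None:
        out.normalized = out.normalized[keep_samples]

    total = out.raw.to_numpy().sum()
    if total > 0:
        pooled = out.raw.sum(axis=1)
        frac = pooled / total
        drop_ab = frac.index[frac < min_frac]
        for gid in drop_ab:
            log.append({
                "entity": gid, "kind": "otu", "rule": "min_frac",
                "value": float(frac[gid]), "threshold": min_frac,
            })
        out = _drop_otus(out, drop_ab)

    cov = out.coverage.reindex(out.raw.index)
    low = (cov["unique_cov"] < min_unique_cov) & (cov["genome_cov"] < min_genome_cov)
    for gid in cov.index[low]:
        log.append({
            "entity": gid, "kind": "otu", "rule": "min_coverage",
            "value": [float(cov.loc[gid, "unique_cov"]), float(cov.loc[gid, "genome_cov"])],
            "threshold": [min_unique_cov, min_genome_cov],
        })
    out = _drop_otus(out, cov.index[low])

    if out.raw.size == 0 or out.raw.to_numpy().sum() == 0:
        warnings.warn("all features or samples removed by filtering", stacklevel=2)
    return out, log


def _drop_otus(table: OtuTable, otus) -> OtuTable:
    keep = table.raw.index.difference(otus)
    table.raw = table.raw.loc[keep]
    table.lineages = table.lineages.loc[keep]
    table.coverage = table.coverage.loc[keep]
    if table.normalized is not None:
        table.normalized = table.normalized.loc[keep]
    return table


def to_relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Convert each sample column to relative abundance (sums to 1)."""
    sums = table.sum(axis=0)
    zero = sums.index[sums == 0]
    if len(zero):
        raise ProfilerError(f"all-zero sample column(s): {list(zero)}")
    return table / sums


# --------------------------------------------------------------------------
# taxa table from per-read LCA
# --------------------------------------------------------------------------

def build_taxa_table(
    hits: pd.DataFrame, refdb: ReferenceDB, threshold: float = DEFAULT_LCA_THRESHOLD
) -> pd.DataFrame:
    """Counts per assigned lineage per sample, from per-read LCA of tie sets.

    Reads with a singleton tie set land at the genome's full resolution;
    tied reads are truncated to their >= threshold consensus.  Features are
    lineage strings.
    """
    if hits.empty:
        return pd.DataFrame(dtype=int)
    sets = _tie_sets(hits)
    lineage_of_set = {
        s: str(assign_lineage(s, refdb, threshold)) for s in sets.unique()
    }
    assigned = sets.map(lineage_of_set)
    df = pd.DataFrame({"sample_id": hits["sample_id"], "lineage": assigned})
    counts = df.groupby(["lineage", "sample_id"], sort=True).size().unstack(fill_value=0)
    counts.columns.name = None
    counts.index.name = "lineage"
    return counts


# --------------------------------------------------------------------------
# functional tables
# --------------------------------------------------------------------------

def build_function_tables(
    hits: pd.DataFrame, refdb: ReferenceDB, relative: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """KO and enzyme tables from gene-level hits.

    KO count = reads whose alignment overlaps a gene annotated with that KO;
    enzyme counts collapse KOs via the KO->enzyme map, a KO mapping to k
    enzymes contributing its full count to each.  With ``relative=True``
    (default) both tables are converted to per-sample relative abundance.
    """
    gene_hits = hits[hits["gene_id"].notna() & (hits["gene_id"] != "-")]
    if gene_hits.empty:
        warnings.warn("no gene-level hits; function tables are empty", stacklevel=2)
        empty = pd.DataFrame(dtype=float)
        return empty, empty.copy()
    unknown = set(gene_hits["gene_id"]) - set(refdb.gene_to_ko)
    if unknown:
        raise ProfilerError(f"gene ids not in reference database: {sorted(unknown)[:5]}")
    kos = gene_hits["gene_id"].map(refdb.gene_to_ko)
    ko_counts = (
        pd.DataFrame({"ko": kos, "sample_id": gene_hits["sample_id"]})
        .groupby(["ko", "sample_id"], sort=True).size().unstack(fill_value=0)
    )
    ko_counts.columns.name = None
    ko_counts.index.name = "ko_id"

    rows = {}
    for ko in ko_counts.index:
        for ec in sorted(refdb.ko_to_enzymes.get(ko, ())):
            if ec in rows:
                rows[ec] = rows[ec] + ko_counts.loc[ko]
            else:
                rows[ec] = ko_counts.loc[ko].copy()
    enzyme_counts = pd.DataFrame(rows).T.sort_index()
    enzyme_counts.index.name = "enzyme_id"

    if relative:
        return to_relative_abundance(ko_counts), to_relative_abundance(enzyme_counts)
    return ko_counts, enzyme_counts


# --------------------------------------------------------------------------
# amplicon: ASV collapse
# --------------------------------------------------------------------------

def collapse_asvs_by_taxonomy(
    asv_table: pd.DataFrame, asv_lineages: pd.Series
) -> pd.DataFrame:
    """Sum ASVs sharing an identical taxonomic assignment into one feature.

    Features of the result are lineage strings; per-sample totals are
    conserved.
    """
    missing = asv_table.index.difference(asv_lineages.index)
    if len(missing):
        raise ProfilerError(f"ASVs without a lineage: {list(missing)[:5]}")
    for lin in asv_lineages.loc[asv_table.index].unique():
        Lineage.parse(str(lin))  # validate
    grouped = asv_table.groupby(asv_lineages.loc[asv_table.index].astype(str), sort=True).sum()
    grouped.index.name = "lineage"
    return grouped
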