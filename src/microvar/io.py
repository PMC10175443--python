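"""Typed readers and writers for the pipeline's on-disk formats.

Everything is UTF-8, tab-delimited with a header row:

* feature table — first column the feature id, optional second column
  ``lineage``, remaining columns one per sample;
* metadata — sample_id, subject, day, week, extraction_rep, libprep_rep,
  modality;
* distance matrix — header of sample ids, first column sample ids, full
  square matrix;
* hit table — sample_id, read_id, tied_genome_ids (";"-joined), position,
  gene_id ("-" when the read hits no gene);
* reference database — a directory of three TSVs (genome manifest, gene
  records, KO->enzyme map);
* variation records — sample_a, sample_b, modality, category, dissimilarity.

Readers validate schema strictly and name the offending row or column in
their error messages; write->read round-trips are identity (floats to
1e-12).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .lineage import Lineage
from .synth import (
    HIT_COLUMNS,
    Gene,
    Genome,
    Modality,
    ReferenceDB,
    SampleMeta,
    design_frame,
)


class FormatError(ValueError):
    """A file does not conform to its documented schema."""


METADATA_COLUMNS = [
    "sample_id", "subject", "day", "week", "extraction_rep", "libprep_rep", "modality",
]


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kw)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: not parseable as TSV ({exc})") from exc


# --------------------------------------------------------------------------
# feature tables
# --------------------------------------------------------------------------

def write_feature_table(
    table: pd.DataFrame, path: str | Path, lineages: pd.Series | None = None
) -> None:
    out = table.copy()
    out.index.name = out.index.name or "feature_id"
    if lineages is not None:
        out.insert(0, "lineage", lineages.reindex(out.index).astype(str))
    out.to_csv(path, sep="\t")


def read_feature_table(path: str | Path) -> tuple[pd.DataFrame, pd.Series | None]:
    """Read a feature table; returns (table, lineages-or-None)."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: feature table needs an id column plus >= 1 sample")
    id_col = raw.columns[0]
    if raw[id_col].duplicated().any():
        dup = raw[id_col][raw[id_col].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    raw = raw.set_index(id_col)
    lineages = None
    if "lineage" in raw.columns:
        lineages = raw.pop("lineage")
        lineages.name = "lineage"
    table = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        try:
            table[col] = pd.to_numeric(raw[col])
        except (TypeError, ValueError) as exc:
            bad = raw[raw[col].apply(lambda v: not _is_number(v))]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric cell in column {col!r}, feature {row!r}"
            ) from exc
    return table, lineages


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


# --------------------------------------------------------------------------
# metadata
# --------------------------------------------------------------------------

def write_metadata(design: list[SampleMeta], path: str | Path) -> None:
    design_frame(design).to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> list[SampleMeta]:
    df = _read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate sample_id {dup!r}")
    out = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                SampleMeta(
                    sample_id=row.sample_id,
                    subject=row.subject,
                    day=int(row.day),
                    week=int(row.week),
                    extraction_rep=int(row.extraction_rep),
                    libprep_rep=int(row.libprep_rep),
                    modality=Modality(row.modality),
                )
            )
        except (ValueError, KeyError) as exc:
            raise FormatError(f"{path}:{lineno}: bad metadata row ({exc})") from exc
    return out


# --------------------------------------------------------------------------
# distance matrices
# --------------------------------------------------------------------------

def write_distance_matrix(D: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(D.data, index=list(D.ids), columns=list(D.ids)).to_csv(
        path, sep="\t", index_label="sample_id"
    )


def read_distance_matrix(path: str | Path, atol: float = 1e-9) -> DistanceMatrix:
    df = _read_tsv(path)
    ids = df.iloc[:, 0].tolist()
    cols = list(df.columns[1:])
    if ids != cols:
        raise FormatError(f"{path}: row ids and column ids differ")
    try:
        mat = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric distance cell ({exc})") from exc
    asym = np.abs(mat - mat.T)
    if asym.max(initial=0.0) > atol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise FormatError(
            f"{path}: asymmetric at row {ids[i]!r} / column {ids[j]!r} "
            f"(|d_ij - d_ji| = {asym[i, j]:.3g})"
        )
    mat = (mat + mat.T) / 2
    np.fill_diagonal(mat, 0.0)
    return DistanceMatrix(mat, ids=ids)


# --------------------------------------------------------------------------
# hit tables
# --------------------------------------------------------------------------

def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits[HIT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_hit_table(path: str | Path, refdb: ReferenceDB | None = None) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in HIT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing hit-table columns {missing}")
    try:
        df["position"] = df["position"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer position ({exc})") from exc
    if refdb is not None:
        known = set(refdb.genomes)
        for lineno, ties in enumerate(df["tied_genome_ids"], start=2):
            for gid in str(ties).split(";"):
                if gid and gid not in known:
                    raise FormatError(f"{path}:{lineno}: unknown genome id {gid!r}")
    return df[HIT_COLUMNS]


# --------------------------------------------------------------------------
# reference database
# --------------------------------------------------------------------------

def write_reference_db(refdb: ReferenceDB, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for gid in refdb.genome_ids:
        g = refdb.genomes[gid]
        rows.append(
            {
                "genome_id": gid,
                "lineage": str(g.lineage),
                "length": g.length,
                "unique_intervals": ";".join(f"{a}-{b}" for a, b in g.unique_intervals),
            }
        )
    pd.DataFrame(rows).to_csv(directory / "genomes.tsv", sep="\t", index=False)
    gene_rows = [
        {"genome_id": gid, "gene_id": gene.gene_id, "start": gene.start,
         "end": gene.end, "ko_id": gene.ko_id}
        for gid in refdb.genome_ids for gene in refdb.genomes[gid].genes
    ]
    pd.DataFrame(gene_rows).to_csv(directory / "genes.tsv", sep="\t", index=False)
    ec_rows = [
        {"ko_id": ko, "enzyme_id": ec}
        for ko in sorted(refdb.ko_to_enzymes)
        for ec in sorted(refdb.ko_to_enzymes[ko])
    ]
    pd.DataFrame(ec_rows).to_csv(directory / "ko2enzyme.tsv", sep="\t", index=False)
    taxa = pd.DataFrame(
        [{"taxon": t, "genome_id": g} for t, g in sorted(refdb.taxon_to_genome.items())]
    )
    taxa.to_csv(directory / "taxa.tsv", sep="\t", index=False)


def read_reference_db(directory: str | Path) -> ReferenceDB:
    directory = Path(directory)
    manifest = _read_tsv(directory / "genomes.tsv")
    genes_df = _read_tsv(directory / "genes.tsv")
    ec_df = _read_tsv(directory / "ko2enzyme.tsv")

    genes_by_genome: dict[str, list[Gene]] = {}
    for lineno, row in enumerate(genes_df.itertuples(index=False), start=2):
        try:
            genes_by_genome.setdefault(row.genome_id, []).append(
                Gene(row.gene_id, int(row.start), int(row.end), row.ko_id)
            )
        except ValueError as exc:
            raise FormatError(f"{directory / 'genes.tsv'}:{lineno}: bad gene row ({exc})") from exc

    genomes: dict[str, Genome] = {}
    for lineno, row in enumerate(manifest.itertuples(index=False), start=2):
        try:
            intervals = tuple(
                tuple(int(x) for x in field.split("-"))
                for field in str(row.unique_intervals).split(";") if field
            )
            genomes[row.genome_id] = Genome(
                genome_id=row.genome_id,
                lineage=Lineage.parse(row.lineage),
                length=int(row.length),
                unique_intervals=intervals,
                genes=tuple(genes_by_genome.get(row.genome_id, ())),
            )
        except (ValueError, KeyError) as exc:
            raise FormatError(
                f"{directory / 'genomes.tsv'}:{lineno}: bad genome row ({exc})"
            ) from exc

    ko_to_enzymes: dict[str, set[str]] = {}
    for row in ec_df.itertuples(index=False):
        ko_to_enzymes.setdefault(row.ko_id, set()).add(row.enzyme_id)

    taxa_path = directory / "taxa.tsv"
    taxon_to_genome: dict[str, str] = {}
    if taxa_path.exists():
        for row in _read_tsv(taxa_path).itertuples(index=False):
            taxon_to_genome[row.taxon] = row.genome_id

    return ReferenceDB(
        genomes=genomes,
        ko_to_enzymes={k: frozenset(v) for k, v in ko_to_enzymes.items()},
        taxon_to_genome=taxon_to_genome,
    )


# --------------------------------------------------------------------------
# variation records, stats, JSON helpers
# --------------------------------------------------------------------------

VARIATION_COLUMNS = ["sample_a", "sample_b", "modality", "category", "dissimilarity"]


def write_variation_records(records: pd.DataFrame, path: str | Path) -> None:
    records[VARIATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_variation_records(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = [c for c in VARIATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    df["dissimilarity"] = df["dissimilarity"].astype(float)
    return df[VARIATION_COLUMNS]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
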