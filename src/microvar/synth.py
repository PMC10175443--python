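"""Synthetic nested-replicate microbiome study generator.

Emulates a crossover benchmark of two sequencing modalities on the same
biological material: for every subject x day x extraction x library-prep
combination there is one latent community composition shared by both
modalities; the shotgun-like measurement observes it directly, while the
amplicon-like measurement sees it through a fixed per-taxon amplification
bias plus extra library-prep-level noise.  Sequencing itself is a
multinomial draw at the configured depth.

The hierarchy of effects is log-additive Gaussian: a global log-abundance
per taxon plus independent per-taxon perturbations at the subject, week,
day, extraction and library-prep levels, pushed through a softmax to give a
composition.  Each sigma therefore controls the dissimilarity contributed
by exactly one level of the design.

For the shotgun path the generator also fabricates a toy reference-genome
database and read-level hit tables (tied best hits with alignment
positions), which downstream profiling consumes in place of a real aligner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from .config import READ_LENGTH, SimulationConfig
from .lineage import Lineage


class Modality(str, Enum):
    AMPLICON = "AMPLICON"
    SHOTGUN = "SHOTGUN"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_MODALITY_SUFFIX = {Modality.AMPLICON: "A", Modality.SHOTGUN: "S"}


def week_of_day(day: int) -> int:
    """Collection week of a study day (days 1-7 -> week 1, 8-14 -> week 2...)."""
    return 1 + (day - 1) // 7


@dataclass(frozen=True)
class SampleMeta:
    """Design coordinates of one sequenced sample."""

    sample_id: str
    subject: str
    day: int
    week: int
    extraction_rep: int
    libprep_rep: int
    modality: Modality

    @property
    def unit_id(self) -> str:
        """Identifier of the modality-agnostic biological unit."""
        return f"{self.subject}.d{self.day}.e{self.extraction_rep}.l{self.libprep_rep}"


@dataclass(frozen=True)
class LatentProfile:
    """Ground-truth composition of one biological unit (sums to 1)."""

    sample_id: str
    composition: np.ndarray

    def __post_init__(self) -> None:
        comp = np.asarray(self.composition, dtype=float)
        if (comp < 0).any():
            raise ValueError("composition entries must be >= 0")
        if abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("composition must sum to 1")
        object.__setattr__(self, "composition", comp)


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int
    end: int  # half-open
    ko_id: str


@dataclass(frozen=True)
class Genome:
    genome_id: str
    lineage: Lineage
    length: int
    unique_intervals: tuple[tuple[int, int], ...]  # half-open, disjoint
    genes: tuple[Gene, ...]

    def __post_init__(self) -> None:
        for s, e in self.unique_intervals:
            if not (0 <= s < e <= self.length):
                raise ValueError(f"{self.genome_id}: interval ({s},{e}) outside [0,{self.length})")
        ivs = sorted(self.unique_intervals)
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"{self.genome_id}: unique intervals overlap")
        if not self.genes:
            raise ValueError(f"{self.genome_id}: every genome needs >= 1 gene")


@dataclass
class ReferenceDB:
    """Toy genome database: one genome per simulated taxon, plus KO->enzyme map."""

    genomes: dict[str, Genome]
    ko_to_enzymes: dict[str, frozenset[str]]
    taxon_to_genome: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.taxon_to_genome:
            self.taxon_to_genome = {g: g for g in self.genomes}
        self.gene_to_ko = {
            gene.gene_id: gene.ko_id for gm in self.genomes.values() for gene in gm.genes
        }

    @property
    def genome_ids(self) -> list[str]:
        return sorted(self.genomes)

    def lineage_of(self, genome_id: str) -> Lineage:
        try:
            return self.genomes[genome_id].lineage
        except KeyError:
            raise KeyError(f"genome {genome_id!r} not in reference database") from None

    def genus_members(self) -> dict[str, list[str]]:
        """Map genus name -> sorted genome ids of that genus."""
        out: dict[str, list[str]] = {}
        for gid in self.genome_ids:
            genus = self.genomes[gid].lineage.at_rank("genus")
            if genus is not None:
                out.setdefault(genus, []).append(gid)
        return out


# --------------------------------------------------------------------------
# design
# --------------------------------------------------------------------------

def simulate_design(config: SimulationConfig) -> list[SampleMeta]:
    """Enumerate the full nested design for both modalities.

    Deterministic given the config: subjects S1..Sn crossed with the study
    days, extraction replicates and library-prep replicates, once per
    modality.
    """
    design: list[SampleMeta] = []
    for modality in (Modality.AMPLICON, Modality.SHOTGUN):
        for si in range(1, config.n_subjects + 1):
            subject = f"S{si}"
            for day in config.days:
                for e in range(1, config.n_extractions + 1):
                    for l in range(1, config.n_libpreps + 1):
                        sid = f"{subject}.d{day}.e{e}.l{l}.{_MODALITY_SUFFIX[modality]}"
                        design.append(
                            SampleMeta(
                                sample_id=sid,
                                subject=subject,
                                day=day,
                                week=week_of_day(day),
                                extraction_rep=e,
                                libprep_rep=l,
                                modality=modality,
                            )
                        )
    return design


def design_frame(design: list[SampleMeta]) -> pd.DataFrame:
    """SampleMeta list as a tidy metadata table indexed by sample_id."""
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in design],
            "subject": [m.subject for m in design],
            "day": [m.day for m in design],
            "week": [m.week for m in design],
            "extraction_rep": [m.extraction_rep for m in design],
            "libprep_rep": [m.libprep_rep for m in design],
            "modality": [m.modality.value for m in design],
        }
    )
    return df.set_index("sample_id")


# --------------------------------------------------------------------------
# latent profiles and measured compositions
# --------------------------------------------------------------------------

def _softmax(logits: np.ndarray) -> np.ndarray:
    z = np.exp(logits - logits.max())
    return z / z.sum()


def simulate_profiles(
    config: SimulationConfig, design: list[SampleMeta]
) -> tuple[list[LatentProfile], dict[str, np.ndarray]]:
    """Draw latent unit compositions and per-sample measured compositions.

    Returns ``(latent, measured)`` where ``latent`` holds one profile per
    biological unit (subject x day x extraction x libprep) and ``measured``
    maps every sample_id in the design to its composition.  The shotgun
    measurement equals the latent composition; the amplicon measurement is
    the latent log-abundance plus the fixed per-taxon amplicon bias and an
    extra per-libprep perturbation, renormalized.

    All effects are drawn from one generator seeded by ``config.seed`` in a
    fixed order, so identical configs give identical profiles, and setting a
    sigma to zero silences its level without disturbing the other draws.
    """
    rng = np.random.default_rng(np.random.SeedSequence([1, config.seed]))
    k = config.n_taxa

    base = rng.normal(0.0, 1.0, k)
    amplicon_bias = rng.normal(0.0, 1.0, k) * config.amplicon_bias_sigma

    subjects = sorted({m.subject for m in design})
    days = sorted({m.day for m in design})
    weeks = sorted({week_of_day(d) for d in days})

    subj_eff = {s: rng.normal(0.0, 1.0, k) * config.sigma_subject for s in subjects}
    week_eff = {
        (s, w): rng.normal(0.0, 1.0, k) * config.sigma_week
        for s in subjects for w in weeks
    }
    day_eff = {
        (s, d): rng.normal(0.0, 1.0, k) * config.sigma_day
        for s in subjects for d in days
    }
    ext_eff = {
        (s, d, e): rng.normal(0.0, 1.0, k) * config.sigma_extraction
        for s in subjects for d in days for e in range(1, config.n_extractions + 1)
    }
    lib_eff = {
        (s, d, e, l): rng.normal(0.0, 1.0, k) * config.sigma_libprep
        for s in subjects for d in days
        for e in range(1, config.n_extractions + 1)
        for l in range(1, config.n_libpreps + 1)
    }
    amp_extra = {
        (s, d, e, l): rng.normal(0.0, 1.0, k) * config.amplicon_extra_libprep_sigma
        for s in subjects for d in days
        for e in range(1, config.n_extractions + 1)
        for l in range(1, config.n_libpreps + 1)
    }

    latent: list[LatentProfile] = []
    latent_logits: dict[str, np.ndarray] = {}
    seen: set[str] = set()
    measured: dict[str, np.ndarray] = {}
    for m in design:
        key = (m.subject, m.day, m.extraction_rep, m.libprep_rep)
        logits = (
            base
            + subj_eff[m.subject]
            + week_eff[(m.subject, m.week)]
            + day_eff[(m.subject, m.day)]
            + ext_eff[(m.subject, m.day, m.extraction_rep)]
            + lib_eff[key]
        )
        if m.unit_id not in seen:
            seen.add(m.unit_id)
            latent_logits[m.unit_id] = logits
            latent.append(LatentProfile(m.unit_id, _softmax(logits)))
        if m.modality is Modality.SHOTGUN:
            measured[m.sample_id] = _softmax(logits)
        else:
            measured[m.sample_id] = _softmax(logits + amplicon_bias + amp_extra[key])
    return latent, measured


def sample_counts(composition: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Multinomial sequencing draw: counts sum to ``depth``."""
    comp = np.asarray(composition, dtype=float)
    if (comp < 0).any():
        raise ValueError("composition entries must be >= 0")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    total = comp.sum()
    if total <= 0:
        raise ValueError("composition must have positive mass")
    return rng.multinomial(depth, comp / total)


# --------------------------------------------------------------------------
# reference database
# --------------------------------------------------------------------------

def taxon_names(n_taxa: int) -> list[str]:
    return [f"T{i + 1:03d}" for i in range(n_taxa)]


def build_reference_db(config: SimulationConfig, rng: np.random.Generator) -> ReferenceDB:
    """Fabricate one toy genome per taxon with a coherent taxonomy.

    Genera hold one or two species so that tied hits within a genus exist
    (the raw material for LCA truncation); families group pairs of genera,
    and phyla partition the genera into >= 2 blocks once there are >= 4 taxa.
    Each genome carries disjoint "unique region" intervals covering
    ``unique_fraction`` of its length and ``n_kos_per_genome`` gene records
    annotated with KO ids drawn from a shared pool; each KO maps to one or
    two enzymes.
    """
    n = config.n_taxa
    lo, hi = config.genome_length_range
    if lo < READ_LENGTH:
        raise ValueError("minimum genome length is shorter than the read length")

    # two species for the first half of genera, one for the rest
    genus_of_taxon: list[int] = []
    g = 0
    remaining = n
    while remaining > 0:
        size = 2 if (g % 2 == 0 and remaining >= 2) else 1
        genus_of_taxon.extend([g] * size)
        remaining -= size
        g += 1
    n_genera = g
    n_phyla = 2 if n >= 4 else 1

    ko_pool = [f"K{i + 1:05d}" for i in range(max(3, (n * config.n_kos_per_genome) // 3))]
    enzyme_pool = [f"EC{i + 1:03d}" for i in range(max(2, len(ko_pool) // 2))]
    ko_to_enzymes: dict[str, frozenset[str]] = {}
    for ko in ko_pool:
        n_ec = int(rng.integers(1, 3))
        ecs = rng.choice(len(enzyme_pool), size=n_ec, replace=False)
        ko_to_enzymes[ko] = frozenset(enzyme_pool[i] for i in ecs)

    genomes: dict[str, Genome] = {}
    taxon_to_genome: dict[str, str] = {}
    species_counter: dict[int, int] = {}
    for t, taxon in enumerate(taxon_names(n)):
        genus = genus_of_taxon[t]
        phylum = genus * n_phyla // n_genera if n_genera else 0
        family = genus // 2
        sp = species_counter.get(genus, 0) + 1
        species_counter[genus] = sp
        lineage = Lineage(
            (
                "Bacteria",
                f"Phy{phylum + 1}",
                f"Cla{phylum + 1}",
                f"Ord{family + 1}",
                f"Fam{family + 1}",
                f"Gen{genus + 1}",
                f"Gen{genus + 1} sp{sp}",
            )
        )
        length = int(rng.integers(lo, hi + 1))
        u_len = max(1, round(config.unique_fraction * length))
        u_start = 0 if u_len >= length else int(rng.integers(0, length - u_len + 1))
        unique_intervals = ((u_start, u_start + u_len),)

        genome_id = f"G{t + 1:03d}"
        genes = []
        n_genes = config.n_kos_per_genome
        slot = length // n_genes
        gene_len = min(900, max(1, slot - 1))
        for j in range(n_genes):
            start = j * slot
            ko = ko_pool[int(rng.integers(0, len(ko_pool)))]
            genes.append(Gene(f"{genome_id}_g{j + 1:03d}", start, start + gene_len, ko))
        genomes[genome_id] = Genome(genome_id, lineage, length, unique_intervals, tuple(genes))
        taxon_to_genome[taxon] = genome_id

    used_kos = {gene.ko_id for gm in genomes.values() for gene in gm.genes}
    return ReferenceDB(
        genomes=genomes,
        ko_to_enzymes={k: v for k, v in ko_to_enzymes.items() if k in used_kos},
        taxon_to_genome=taxon_to_genome,
    )


# --------------------------------------------------------------------------
# read-level hit tables
# --------------------------------------------------------------------------

HIT_COLUMNS = ["sample_id", "read_id", "tied_genome_ids", "position", "gene_id"]


def generate_hit_table(
    counts: pd.DataFrame,
    refdb: ReferenceDB,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Emulate post-alignment tied best hits for every shotgun read.

    ``counts`` is a taxa x samples integer table.  Each read of a taxon hits
    that taxon's genome at a uniform start position; with probability
    ``config.p_tie`` (and only when the genus holds more than one genome)
    the read is reported as tied across all same-genus genomes.  Reads whose
    interval overlaps an annotated gene carry its gene_id.  One row per
    read; ``tied_genome_ids`` is a ";"-joined sorted id list.
    """
    for taxon in counts.index:
        if taxon not in refdb.taxon_to_genome:
            raise KeyError(f"taxon {taxon!r} has no genome in the reference database")

    genus_map = refdb.genus_members()
    frames: list[pd.DataFrame] = []
    for sample in counts.columns:
        col = counts[sample]
        for taxon, c in col.items():
            c = int(c)
            if c == 0:
                continue
            gid = refdb.taxon_to_genome[taxon]
            genome = refdb.genomes[gid]
            genus = genome.lineage.at_rank("genus")
            partners = genus_map.get(genus, [gid])
            tie_possible = len(partners) > 1
            tied = (
                rng.random(c) < config.p_tie if (tie_possible and config.p_tie > 0)
                else np.zeros(c, dtype=bool)
            )
            min_len = min(refdb.genomes[p].length for p in partners)
            pos_plain = rng.integers(0, genome.length - READ_LENGTH + 1, size=c)
            pos_tied = rng.integers(0, min_len - READ_LENGTH + 1, size=c)
            positions = np.where(tied, pos_tied, pos_plain)

            # genes are laid out in fixed non-overlapping slots; locate by slot
            gene_ids = np.full(c, "-", dtype=object)
            starts = np.array([g.start for g in genome.genes])
            ends = np.array([g.end for g in genome.genes])
            idx = np.searchsorted(starts, positions, side="right") - 1
            read_end = positions + READ_LENGTH
            # read overlaps gene idx if it starts before that gene's end...
            ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
            # ...or reaches into the next gene slot
            nxt = idx + 1
            reaches_next = (nxt < len(starts)) & (read_end > starts[np.clip(nxt, None, len(starts) - 1)])
            gene_names = np.array([g.gene_id for g in genome.genes], dtype=object)
            gene_ids[ok] = gene_names[idx[ok]]
            fill = (~ok) & reaches_next
            gene_ids[fill] = gene_names[nxt[fill]]

            tie_str = ";".join(sorted(partners))
            frames.append(
                pd.DataFrame(
                    {
                        "sample_id": sample,
                        "read_id": [f"{sample}:{taxon}:r{i}" for i in range(c)],
                        "tied_genome_ids": np.where(tied, tie_str, gid),
                        "position": positions,
                        "gene_id": gene_ids,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=HIT_COLUMNS)
    return pd.concat(frames, ignore_index=True)[HIT_COLUMNS]


# --------------------------------------------------------------------------
# whole-dataset convenience
# --------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    """Everything one simulated study produces."""

    config: SimulationConfig
    design: list[SampleMeta]
    latent: list[LatentProfile]
    measured: dict[str, np.ndarray]
    refdb: ReferenceDB | None
    shotgun_counts: pd.DataFrame       # true-taxon counts (taxa x shotgun samples)
    amplicon_counts: pd.DataFrame      # ASV counts (ASVs x amplicon samples)
    asv_lineages: pd.Series            # ASV id -> lineage string
    hits: pd.DataFrame | None          # read-level hit table (shotgun)

    @property
    def metadata(self) -> pd.DataFrame:
        return design_frame(self.design)


def _amplicon_asvs(
    config: SimulationConfig, refdb_lineages: list[Lineage], rng: np.random.Generator
) -> tuple[list[str], pd.Series, np.ndarray, np.ndarray]:
    """Lay out 1-2 ASVs per taxon with genus-level lineages (species for a
    p_species_16s fraction), returning ids, lineages, the taxon index of each
    ASV and the within-taxon split fraction."""
    ids: list[str] = []
    lineages: list[str] = []
    taxon_idx: list[int] = []
    fracs: list[float] = []
    counter = 0
    for t in range(config.n_taxa):
        full = refdb_lineages[t]
        resolved = rng.random() < config.p_species_16s
        lin = full if resolved else full.truncate(6)
        n_asv = 2 if rng.random() < 0.5 else 1
        split = float(rng.uniform(0.2, 0.8)) if n_asv == 2 else 1.0
        for j, frac in enumerate([split, 1.0 - split][:n_asv]):
            counter += 1
            ids.append(f"ASV{counter:04d}")
            lineages.append(str(lin))
            taxon_idx.append(t)
            fracs.append(frac)
    return ids, pd.Series(lineages, index=ids, name="lineage"), np.array(taxon_idx), np.array(fracs)


def simulate_dataset(config: SimulationConfig, with_hits: bool = True) -> SimulatedDataset:
    """Run the full generator: design, profiles, reference db, count tables
    and (optionally) the shotgun hit table.

    All randomness derives from ``config.seed`` through per-stage child
    seeds, so the output is bit-for-bit reproducible.
    """
    design = simulate_design(config)
    latent, measured = simulate_profiles(config, design)

    rng_db = np.random.default_rng(np.random.SeedSequence([2, config.seed]))
    refdb = build_reference_db(config, rng_db)
    taxa = taxon_names(config.n_taxa)
    lineages = [refdb.genomes[refdb.taxon_to_genome[t]].lineage for t in taxa]

    rng_seq = np.random.default_rng(np.random.SeedSequence([3, config.seed]))
    shotgun_ids = [m.sample_id for m in design if m.modality is Modality.SHOTGUN]
    amplicon_ids = [m.sample_id for m in design if m.modality is Modality.AMPLICON]

    shotgun_counts = pd.DataFrame(
        {sid: sample_counts(measured[sid], config.read_depth_shotgun, rng_seq)
         for sid in shotgun_ids},
        index=taxa,
    )

    asv_ids, asv_lineages, asv_taxon, asv_frac = _amplicon_asvs(config, lineages, rng_seq)
    amplicon_counts = pd.DataFrame(
        {
            sid: sample_counts(
                measured[sid][asv_taxon] * asv_frac, config.read_depth_amplicon, rng_seq
            )
            for sid in amplicon_ids
        },
        index=asv_ids,
    )

    hits = None
    if with_hits:
        rng_hits = np.random.default_rng(np.random.SeedSequence([4, config.seed]))
        hits = generate_hit_table(shotgun_counts, refdb, config, rng_hits)

    return SimulatedDataset(
        config=config,
        design=design,
        latent=latent,
        measured=measured,
        refdb=refdb,
        shotgun_counts=shotgun_counts,
        amplicon_counts=amplicon_counts,
        asv_lineages=asv_lineages,
        hits=hits,
    )
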