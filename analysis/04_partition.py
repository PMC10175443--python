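#!/usr/bin/env python
"""Partition pairwise dissimilarities into the five variation sources and
summarize cross-modality agreement.

Classifies every within-modality sample pair (library prep, extraction,
daily, weekly, subject), computes genus-level concordance between matched
amplicon/shotgun profiles (absent genera as zeroes) and the
abundance-weighted taxonomic-resolution profile of each modality.
"""

from pathlib import Path

from microvar import io
from microvar.partition import (
    category_counts,
    genus_concordance,
    partition_dissimilarities,
    resolution_summary,
    top_taxa,
)
from microvar.profiler import to_relative_abundance

STUDY = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    meta = io.read_metadata(STUDY / "metadata.tsv")
    by_id = {m.sample_id: m for m in meta}

    for name in ("shotgun_taxa", "amplicon_taxa", "shotgun_enzyme"):
        D = io.read_distance_matrix(STUDY / f"{name}_braycurtis.tsv")
        records = partition_dissimilarities(D, by_id)
        io.write_variation_records(records, STUDY / f"{name}_variation.tsv")
        med = records.groupby("category")["dissimilarity"].median()
        counts = category_counts(records)
        print(f"{name}: pairs {counts}; medians "
              + ", ".join(f"{c}={med[c]:.3f}" for c in med.index))

    taxa_sho, _ = io.read_feature_table(STUDY / "shotgun_taxa_counts.tsv")
    taxa_amp, _ = io.read_feature_table(STUDY / "amplicon_taxa_counts.tsv")
    r, rho, n = genus_concordance(
        to_relative_abundance(taxa_amp), to_relative_abundance(taxa_sho), meta
    )
    io.write_json({"pearson_r": r, "spearman_rho": rho, "n_cells": n},
                  STUDY / "genus_concordance.json")
    print(f"genus concordance over {n} cells: r = {r:.3f}, rho = {rho:.3f}")

    res = {"shotgun": resolution_summary(taxa_sho),
           "amplicon": resolution_summary(taxa_amp)}
    io.write_json(res, STUDY / "resolution_summary.json")
    print(f"reads at species level or deeper: "
          f"shotgun {100 * res['shotgun']['species']:.1f}%, "
          f"amplicon {100 * res['amplicon']['species']:.1f}%")

    top = top_taxa(to_relative_abundance(taxa_sho), n=20)
    top.to_csv(STUDY / "shotgun_top_taxa.tsv", sep="\t")
    print(f"top taxon: {top.index[0]} "
          f"(mean {100 * top['mean_abundance'].iloc[0]:.1f}%)")


if __name__ == "__main__":
    main()
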