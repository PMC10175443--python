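#!/usr/bin/env python
"""Rarefy the taxa tables and compute alpha diversity, Bray-Curtis and PCoA.

Each modality's taxa table is rarefied to its own lowest sample depth, then
summarized with Shannon/Chao1/observed features, a Bray-Curtis matrix and a
2-axis principal-coordinates ordination; the enzyme table yields the
functional Bray-Curtis matrix.
"""

from pathlib import Path

import numpy as np

from microvar import io
from microvar.diversity import alpha_diversity_frame, bray_curtis_matrix, pcoa, rarefy
from microvar.profiler import to_relative_abundance

STUDY = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    rng = np.random.default_rng(5)
    for name in ("shotgun_taxa", "amplicon_taxa"):
        counts, _ = io.read_feature_table(STUDY / f"{name}_counts.tsv")
        rare = rarefy(counts, rng=rng)
        rel = to_relative_abundance(rare)
        alpha = alpha_diversity_frame(rare)
        D = bray_curtis_matrix(rel)
        res = pcoa(D, n_axes=2)
        io.write_feature_table(rare, STUDY / f"{name}_rarefied.tsv")
        alpha.to_csv(STUDY / f"{name}_alpha.tsv", sep="\t", index_label="sample_id")
        io.write_distance_matrix(D, STUDY / f"{name}_braycurtis.tsv")
        res.coordinates.to_csv(STUDY / f"{name}_pcoa.tsv", sep="\t",
                               index_label="sample_id")
        print(f"{name}: rarefied to {int(rare.sum().iloc[0])} reads/sample, "
              f"PC1 {100 * res.proportion_explained[0]:.1f}%, "
              f"PC2 {100 * res.proportion_explained[1]:.1f}%")

    enzyme_rel, _ = io.read_feature_table(STUDY / "shotgun_enzyme_relabund.tsv")
    D = bray_curtis_matrix(enzyme_rel)
    io.write_distance_matrix(D, STUDY / "shotgun_enzyme_braycurtis.tsv")
    print(f"enzyme Bray-Curtis over {len(D.ids)} samples written")


if __name__ == "__main__":
    main()
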