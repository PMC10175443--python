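#!/usr/bin/env python
"""Run the statistical battery on the partitioned study.

Per modality: subject-level dispersion homogeneity and PERMANOVA on
Bray-Curtis, Kruskal-Wallis + Dunn (BH) on alpha diversity by subject and
on dissimilarities by variation category; across modalities: two-way ANOVA
(modality x technical category) and per-category pooled t-tests.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from microvar import io
from microvar.partition import TECHNICAL_CATEGORIES
from microvar.stats import (
    betadisper,
    dunn_posthoc,
    kruskal_wallis,
    permanova,
    t_test,
    two_way_anova,
)

STUDY = Path(__file__).resolve().parents[1] / "results" / "study"


def main() -> None:
    meta = {m.sample_id: m for m in io.read_metadata(STUDY / "metadata.tsv")}
    rng = np.random.default_rng(6)
    results = {}

    for name in ("shotgun_taxa", "amplicon_taxa", "shotgun_enzyme"):
        D = io.read_distance_matrix(STUDY / f"{name}_braycurtis.tsv")
        subjects = [meta[sid].subject for sid in D.ids]
        disp, _ = betadisper(D, subjects, n_perm=999, rng=rng)
        perm = permanova(D, subjects, n_perm=999, rng=rng)
        results[f"{name}/betadisper_subject"] = disp.to_dict()
        results[f"{name}/permanova_subject"] = perm.to_dict()
        print(f"{name}: betadisper p = {disp.p_value:.3f}; "
              f"PERMANOVA R2 = {perm.r_squared:.4f}, p = {perm.p_value:.3f}")

    for name in ("shotgun_taxa", "amplicon_taxa"):
        alpha = pd.read_csv(STUDY / f"{name}_alpha.tsv", sep="\t", index_col=0)
        subjects = [meta[sid].subject for sid in alpha.index]
        kw = kruskal_wallis(alpha["shannon"].to_numpy(), subjects)
        results[f"{name}/kruskal_shannon_subject"] = kw.to_dict()
        records = io.read_variation_records(STUDY / f"{name}_variation.tsv")
        kw_cat = kruskal_wallis(records["dissimilarity"].to_numpy(), records["category"])
        dunn = dunn_posthoc(records["dissimilarity"].to_numpy(), records["category"])
        results[f"{name}/kruskal_category"] = kw_cat.to_dict()
        results[f"{name}/dunn_category"] = [d.to_dict() for d in dunn]
        sig = sum(1 for d in dunn if d.p_adjusted is not None and d.p_adjusted < 0.05)
        print(f"{name}: Shannon-by-subject KW p = {kw.p_value:.2e}; "
              f"category KW p = {kw_cat.p_value:.2e}; "
              f"{sig}/{len(dunn)} Dunn pairs significant (padj < 0.05)")

    tech = pd.concat([
        io.read_variation_records(STUDY / "shotgun_taxa_variation.tsv"),
        io.read_variation_records(STUDY / "amplicon_taxa_variation.tsv"),
    ], ignore_index=True)
    tech = tech[tech["category"].isin(TECHNICAL_CATEGORIES)]
    fa, fb = two_way_anova(tech["dissimilarity"].to_numpy(),
                           tech["modality"], tech["category"])
    results["cross/two_way_anova_modality"] = fa.to_dict()
    results["cross/two_way_anova_category"] = fb.to_dict()
    print(f"two-way ANOVA: modality p = {fa.p_value:.2e}, category p = {fb.p_value:.2e}")
    for cat in TECHNICAL_CATEGORIES:
        sub = tech[tech["category"] == cat]
        amp = sub[sub["modality"] == "AMPLICON"]["dissimilarity"].to_numpy()
        sho = sub[sub["modality"] == "SHOTGUN"]["dissimilarity"].to_numpy()
        res = t_test(amp, sho)
        results[f"cross/t_test_{cat.lower()}"] = res.to_dict()
        print(f"t-test {cat.lower()} (amplicon vs shotgun): "
              f"t = {res.statistic:.2f}, p = {res.p_value:.2e}")

    io.write_json(results, STUDY / "stats.json")
    print(f"wrote {len(results)} analyses -> {STUDY / 'stats.json'}")


if __name__ == "__main__":
    main()
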