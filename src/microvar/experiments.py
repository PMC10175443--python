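"""Replicate simulation studies over the nested design.

These drive the headline qualitative claims on synthetic data:

* :func:`category_recovery_study` — with subject variance above day/week
  variance above technical variance, the median Bray-Curtis per category
  should order technical < daily/weekly < subject;
* :func:`modality_power_study` — with amplicon-only extra technical noise
  switched on, pooled-variance t-tests should detect higher amplicon than
  shotgun technical variation;
* :func:`type_one_error_study` — under a global null, PERMANOVA and the
  t-test should reject at about their nominal level.

Each replicate runs the composition -> multinomial -> relative-abundance ->
Bray-Curtis -> partition path; the read-level hit-table machinery is not
needed to measure these quantities and is exercised elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .diversity import bray_curtis_matrix
from .partition import TECHNICAL_CATEGORIES, partition_dissimilarities
from .stats import permanova, t_test
from .synth import Modality, sample_counts, simulate_design, simulate_profiles


def _measured_count_table(config: SimulationConfig, seed: int, modality: Modality) -> tuple:
    cfg = config.replace(seed=seed)
    design = [m for m in simulate_design(cfg) if m.modality is modality]
    full_design = simulate_design(cfg)
    _, measured = simulate_profiles(cfg, full_design)
    rng = np.random.default_rng(np.random.SeedSequence([3, seed]))
    depth = (
        cfg.read_depth_shotgun if modality is Modality.SHOTGUN else cfg.read_depth_amplicon
    )
    table = pd.DataFrame(
        {m.sample_id: sample_counts(measured[m.sample_id], depth, rng) for m in design}
    )
    return table, design


def variation_records_for(
    config: SimulationConfig, seed: int, modality: Modality
) -> pd.DataFrame:
    """Simulate one replicate and partition its Bray-Curtis dissimilarities."""
    table, design = _measured_count_table(config, seed, modality)
    rel = table / table.sum(axis=0)
    D = bray_curtis_matrix(rel)
    return partition_dissimilarities(D, design)


@dataclass
class RecoveryResult:
    n_replicates: int
    n_ordered: int
    median_frames: list[pd.Series]

    @property
    def fraction_ordered(self) -> float:
        return self.n_ordered / self.n_replicates


def category_recovery_study(
    config: SimulationConfig,
    n_replicates: int = 20,
    seed: int = 0,
    modality: Modality = Modality.SHOTGUN,
) -> RecoveryResult:
    """Fraction of replicates whose median category dissimilarities order
    technical < daily/weekly < subject.

    The ordering holds when max(median LIBPREP, median EXTRACTION) <
    min(median DAILY, median WEEKLY) and max(median DAILY, median WEEKLY) <
    median SUBJECT.
    """
    root = np.random.SeedSequence([10, seed])
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(n_replicates)]
    n_ordered = 0
    medians = []
    for rep_seed in child_seeds:
        records = variation_records_for(config, rep_seed, modality)
        med = records.groupby("category")["dissimilarity"].median()
        medians.append(med)
        tech = max(med.get("LIBPREP", np.inf), med.get("EXTRACTION", np.inf))
        bio_low = min(med.get("DAILY", -np.inf), med.get("WEEKLY", -np.inf))
        bio_high = max(med.get("DAILY", np.inf), med.get("WEEKLY", np.inf))
        subj = med.get("SUBJECT", -np.inf)
        if tech < bio_low and bio_high < subj:
            n_ordered += 1
    return RecoveryResult(n_replicates, n_ordered, medians)


@dataclass
class PowerResult:
    n_replicates: int
    n_detected: int
    p_values: list[float]

    @property
    def power(self) -> float:
        return self.n_detected / self.n_replicates


def modality_power_study(
    config: SimulationConfig,
    n_replicates: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
) -> PowerResult:
    """Power of the t-test to detect amplicon > shotgun technical variation.

    Per replicate, technical-pair dissimilarities (library-prep plus
    extraction pairs) are pooled per modality and compared with a one-sided
    pooled-variance t-test (amplicon mean greater).  A replicate counts as a
    detection when p < alpha.
    """
    root = np.random.SeedSequence([11, seed])
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in root.spawn(n_replicates)]
    n_detected = 0
    p_values = []
    for rep_seed in child_seeds:
        rec_s = variation_records_for(config, rep_seed, Modality.SHOTGUN)
        rec_a = variation_records_for(config, rep_seed, Modality.AMPLICON)
        tech_s = rec_s[rec_s["category"].isin(TECHNICAL_CATEGORIES)]["dissimilarity"]
        tech_a = rec_a[rec_a["category"].isin(TECHNICAL_CATEGORIES)]["dissimilarity"]
        res = t_test(tech_a.to_numpy(), tech_s.to_numpy())
        # one-sided: amplicon mean greater
        p = res.p_value / 2 if res.statistic > 0 else 1 - res.p_value / 2
        p_values.append(float(p))
        if p < alpha:
            n_detected += 1
    return PowerResult(n_replicates, n_detected, p_values)


@dataclass
class TypeOneResult:
    n_datasets: int
    permanova_rejections: int
    t_test_rejections: int

    @property
    def permanova_rate(self) -> float:
        return self.permanova_rejections / self.n_datasets

    @property
    def t_test_rate(self) -> float:
        return self.t_test_rejections / self.n_datasets


def type_one_error_study(
    n_datasets: int = 500,
    seed: int = 0,
    n_samples: int = 12,
    n_features: int = 8,
    n_groups: int = 2,
    n_perm: int = 199,
    alpha: float = 0.05,
) -> TypeOneResult:
    """Rejection rates of PERMANOVA and the t-test under a global null.

    Each dataset draws all samples from one Dirichlet community (no group
    effect), computes Bray-Curtis and applies both tests at level alpha.
    """
    rng = np.random.default_rng(np.random.SeedSequence([12, seed]))
    groups = np.repeat(np.arange(n_groups), n_samples // n_groups)
    perm_rej = 0
    t_rej = 0
    for _ in range(n_datasets):
        base = rng.dirichlet(np.ones(n_features) * 2.0)
        counts = rng.multinomial(200, base, size=n_samples)
        rel = pd.DataFrame((counts / counts.sum(axis=1, keepdims=True)).T)
        rel.columns = [f"s{i}" for i in range(n_samples)]
        D = bray_curtis_matrix(rel)
        res = permanova(D, groups, n_perm=n_perm, rng=rng)
        if res.p_value < alpha:
            perm_rej += 1
        values = rng.normal(size=n_samples)
        tres = t_test(values[groups == 0], values[groups == 1])
        if tres.p_value < alpha:
            t_rej += 1
    return TypeOneResult(n_datasets, perm_rej, t_rej)
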