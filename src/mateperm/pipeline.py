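"""End-to-end orchestration: consistency → effects → associations → fathers.

All stage seeds are spawned deterministically from one master seed, so a
fixed (input, config, seed) triple reproduces every output byte-for-byte.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association_measures import association_table, measure_equivalence
from .consistency_core import consistency_table
from .father_contrast import father_contrast_tables
from .shared_cumulative import (CumulativeResult, SharedEffectTable,
                                build_shared_effect_table, cumulative_effect)
from .stepwise_effect import stepwise_effect_size
from .trait_model_io import (CohortTable, format_p, load_cohort,
                             write_results_tables)
from .consistency_core import permutation_null


@dataclass
class RunConfig:
    input_path: str
    registry_path: str | None = None
    out_dir: str = "results"
    n_perm: int = 10_000
    n_effect_runs: int = 10_000
    n_resid_runs: int = 1_000
    seed: int = 0
    alpha: float = 0.05
    traits: Sequence[str] | None = None
    skip_shared: bool = False  # the pairwise stage dominates run time

    def __post_init__(self) -> None:
        for name in ("n_perm", "n_effect_runs", "n_resid_runs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def stage_seeds(master_seed: int, n: int) -> list[int]:
    """Derive independent per-stage seeds as a pure function of the master seed."""
    return [int(s.generate_state(1)[0] % (2**31 - 1))
            for s in np.random.SeedSequence(master_seed).spawn(n)]


def run_all(config: RunConfig, cohort: CohortTable | None = None) -> dict:
    """Execute the full analysis and write the result tables + run manifest."""
    if cohort is None:
        cohort = load_cohort(config.input_path, config.registry_path)
    traits = list(config.traits) if config.traits else cohort.registry.names
    seeds = stage_seeds(config.seed, 4)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # 1) consistency index + permutation test
    cons = consistency_table(cohort, traits, n_perm=config.n_perm, seed=seeds[0])

    # 2) relocation effect sizes (reuse each trait's null mean as target)
    eff_rng = np.random.default_rng(seeds[1])
    effects = {}
    for row in cons:
        null = permutation_null(cohort, row.trait, n_perm=max(200, config.n_perm // 10),
                                seed=int(eff_rng.integers(2**31 - 1)))
        effects[row.trait] = stepwise_effect_size(
            cohort, row.trait, null, n_runs=config.n_effect_runs,
            seed=int(eff_rng.integers(2**31 - 1)))

    # 3) correlational measures + equivalence
    assoc = {r.trait: r for r in association_table(cohort, traits)}
    table1 = pd.DataFrame([{
        "trait": r.trait,
        "observed_delta": r.observed_delta,
        "expected_delta": r.expected_delta,
        "expected_sd": r.expected_sd,
        "p": r.p, "p_adj": r.p_adj, "p_formatted": format_p(r.p),
        "effect_pct": effects[r.trait].effect_pct,
        "ci_lo": effects[r.trait].ci_lo, "ci_hi": effects[r.trait].ci_hi,
        "icc_pct": assoc[r.trait].icc_pct, "pearson_r": assoc[r.trait].pearson_r,
        "n_respondents_informative": r.n_respondents_informative,
        "n_partners_informative": r.n_partners_informative,
    } for r in cons])
    equiv = (measure_equivalence(table1[["effect_pct", "icc_pct", "pearson_r"]])
             if len(table1) >= 3 else None)

    # 4) shared + cumulative effects
    shared_table: SharedEffectTable | None = None
    cumulative: CumulativeResult | None = None
    if not config.skip_shared and len(traits) >= 2:
        shared_table = build_shared_effect_table(
            cohort, traits, n_runs=config.n_resid_runs,
            n_perm=max(200, config.n_perm // 10), seed=seeds[2])
        cumulative = cumulative_effect(shared_table)

    # 5) father contrasts
    excl, models = father_contrast_tables(cohort, traits, n_perm=config.n_perm,
                                          seed=seeds[3])
    table3 = pd.DataFrame([{**asdict(r), "p_formatted": format_p(r.p)} for r in excl])
    mean_rows = {r.trait: r for r in models if r.kind == "mean"}
    var_rows = {r.trait: r for r in models if r.kind == "variance"}
    table4 = pd.DataFrame([{
        "trait": t,
        "mean_intercept_nonfather": mean_rows[t].intercept_nonfather,
        "mean_effect_father": mean_rows[t].effect_father,
        "mean_se": mean_rows[t].se, "mean_p": mean_rows[t].p,
        "mean_p_adj": mean_rows[t].p_adj,
        "var_intercept_nonfather": var_rows[t].intercept_nonfather,
        "var_effect_father": var_rows[t].effect_father,
        "var_se": var_rows[t].se, "var_p": var_rows[t].p,
        "var_p_adj": var_rows[t].p_adj,
    } for t in traits])

    written = write_results_tables({
        "table1_consistency.csv": table1,
        "table3_father_exclusion.csv": table3,
        "table4_father_models.csv": table4,
    }, out_dir)
    if shared_table is not None:
        shared_table.to_csv(out_dir / "table2_shared_effects.csv")
        written.append(out_dir / "table2_shared_effects.csv")

    manifest = {
        "mateperm_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_perm": config.n_perm,
        "n_effect_runs": config.n_effect_runs,
        "n_resid_runs": config.n_resid_runs,
        "alpha": config.alpha,
        "traits": traits,
        "n_respondents": cohort.n_respondents,
        "n_partners": cohort.n_partners,
        "equivalence": asdict(equiv) if equiv else None,
        "cumulative": asdict(cumulative) if cumulative else None,
        "tables": [p.name for p in written],
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return {
        "table1": table1, "table3": table3, "table4": table4,
        "shared": shared_table, "cumulative": cumulative,
        "equivalence": equiv, "manifest": manifest,
    }


def run_cumulative_from_table(table_path: str | Path,
                              order: Sequence[str] | None = None) -> CumulativeResult:
    """Cumulative effect size directly from a table-2-shaped CSV (no resampling)."""
    table = SharedEffectTable.from_csv(table_path)
    return cumulative_effect(table, order=order)
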