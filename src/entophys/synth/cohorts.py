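"""Synthetic multi-animal cohorts for the mixed-model stage.

Responses follow the hierarchical model the statistics module fits:

    y_ijk = mu + genotype + age + sex + setup (fixed)
            + u_i (animal, iid Normal)
            + within-cell repeated structure + residual

so that estimated effects and their coverage can be checked against known
truth.  The same seed always yields a byte-identical table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class CohortSpec:
    """Design and effect sizes for one simulated cohort.

    Fixed-effect sizes are additive shifts applied to the second level of
    each factor (e.g. ``genotype_effect`` is the +/+ minus -/- shift).
    ``within_levels`` > 1 adds a repeated factor per cell with either
    compound-symmetry or per-level heteroscedastic ("diagonal") residuals.
    """

    n_animals_per_genotype: int = 20
    cells_per_animal: int = 4
    genotypes: tuple[str, str] = ("-/-", "+/+")
    grand_mean: float = 0.8
    genotype_effect: float = 0.0
    age_effect: float = 0.0
    sex_effect: float = 0.0
    setup_effect: float = 0.0
    animal_sd: float = 0.03
    residual_sd: float = 0.05
    within_levels: int = 1
    within_name: str = "ap_number"
    within_effects: Optional[tuple[float, ...]] = None
    within_structure: str = "compound_symmetry"   # or "diagonal"
    cell_sd: float = 0.0          # CS: shared cell-level deviation
    level_sds: Optional[tuple[float, ...]] = None  # diagonal: per level
    response_name: str = "sag_ratio"
    seed: int = 0


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Long-format cohort table plus the ground-truth effect record."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for gi, genotype in enumerate(spec.genotypes):
        for ai in range(spec.n_animals_per_genotype):
            animal = f"rat{gi}{ai:03d}"
            age = ("1mo", "3mo")[int(rng.integers(2))]
            sex = ("F", "M")[int(rng.integers(2))]
            setup = ("setup1", "setup2")[int(rng.integers(2))]
            u = rng.normal(0.0, spec.animal_sd)
            for ci in range(spec.cells_per_animal):
                cell = f"{animal}c{ci}"
                base = (
                    spec.grand_mean
                    + (spec.genotype_effect if gi == 1 else 0.0)
                    + (spec.age_effect if age == "3mo" else 0.0)
                    + (spec.sex_effect if sex == "M" else 0.0)
                    + (spec.setup_effect if setup == "setup2" else 0.0)
                    + u
                )
                if spec.within_levels <= 1:
                    y = base + rng.normal(0.0, spec.residual_sd)
                    rows.append((animal, cell, genotype, age, sex, setup,
                                 None, y))
                else:
                    cell_dev = rng.normal(0.0, spec.cell_sd) \
                        if spec.within_structure == "compound_symmetry" \
                        else 0.0
                    for li in range(spec.within_levels):
                        shift = (spec.within_effects[li]
                                 if spec.within_effects is not None else 0.0)
                        sd = (spec.level_sds[li]
                              if spec.level_sds is not None
                              else spec.residual_sd)
                        y = base + shift + cell_dev + rng.normal(0.0, sd)
                        rows.append((animal, cell, genotype, age, sex,
                                     setup, li + 1, y))
    table = pd.DataFrame(
        rows,
        columns=["animal_id", "cell_id", "genotype", "age", "sex",
                 "setup", spec.within_name, spec.response_name],
    )
    if spec.within_levels <= 1:
        table = table.drop(columns=[spec.within_name])
    truth = {
        "grand_mean": spec.grand_mean,
        "genotype_effect": spec.genotype_effect,
        "age_effect": spec.age_effect,
        "sex_effect": spec.sex_effect,
        "setup_effect": spec.setup_effect,
        "animal_sd": spec.animal_sd,
        "residual_sd": spec.residual_sd,
        "within_structure": spec.within_structure,
        "seed": spec.seed,
    }
    return table, truth
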