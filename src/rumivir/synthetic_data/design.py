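"""Crossover feeding designs and diet composition covariates."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from rumivir.errors import DesignError

#: Chemical composition of the four dietary treatments (percent dry
#: matter unless noted), columns are diet identifiers.
_DIET_TABLE_ROWS = {
    "relative_feed_value": (1100.14, 1378.78, 712.65, 252.00),
    "tdn": (81.43, 82.65, 78.50, 73.30),
    "adf": (5.39, 4.91, 9.28, 15.25),
    "ndf": (11.22, 10.14, 19.25, 25.45),
    "crude_protein": (8.74, 12.16, 17.96, 17.17),
    "nitrate_ppm": (25.75, 25.75, 25.75, 19.00),
    "ca": (0.08, 0.07, 0.09, 0.18),
    "p": (0.34, 0.82, 0.60, 0.56),
    "k": (0.63, 1.33, 0.97, 1.25),
    "mg": (0.14, 0.31, 0.23, 0.25),
    "zn": (24.90, 123.47, 38.51, 40.15),
    "fe": (55.91, 92.93, 125.22, 197.25),
    "mn": (10.84, 18.58, 16.32, 21.60),
    "cu": (2.57, 4.16, 4.14, 6.52),
    "s": (0.11, 0.23, 0.26, 0.26),
    "na": (0.03, 0.17, 0.17, 0.13),
    "mo": (0.24, 0.38, 0.51, 0.51),
}

_DIET_IDS = ("Corn", "27CDS", "40MDGS", "55CS")

#: Literal steer-by-period diet layout of the feeding trial.
_BUILTIN_LAYOUT = {
    "346": ("27CDS", "Corn", "40MDGS", "55CS"),
    "3244": ("27CDS", "Corn", "40MDGS", "55CS"),
    "222": ("55CS", "40MDGS", "Corn", "27CDS"),
    "3257": ("40MDGS", "27CDS", "55CS", "Corn"),
    "259": ("Corn", "55CS", "27CDS", "40MDGS"),
}


@dataclass
class StudyDesign:
    """A sample <-> (steer, period, diet) mapping plus diet covariates.

    Attributes
    ----------
    samples : pd.DataFrame
        One row per sample with columns ``sample_id``, ``steer``,
        ``period`` (int) and ``diet``.
    diet_table : pd.DataFrame
        Covariates (rows) by diet id (columns); all finite and
        non-negative.
    """

    samples: pd.DataFrame
    diet_table: pd.DataFrame = field(default_factory=lambda: builtin_diet_table())

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        required = {"sample_id", "steer", "period", "diet"}
        missing = required - set(self.samples.columns)
        if missing:
            raise DesignError(f"sample table missing columns: {sorted(missing)}")
        if self.samples["sample_id"].duplicated().any():
            raise DesignError("duplicate sample ids")
        pairs = self.samples.groupby(["steer", "period"])["diet"].nunique()
        if (pairs > 1).any():
            raise DesignError("a (steer, period) pair maps to more than one diet")
        per_steer = self.samples.groupby(["steer", "diet"]).size()
        if (per_steer > 1).any():
            raise DesignError("a steer repeats a diet")
        vals = self.diet_table.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or (vals < 0).any():
            raise DesignError("diet covariates must be finite and non-negative")
        unknown = set(self.samples["diet"]) - set(self.diet_table.columns)
        if unknown:
            raise DesignError(f"diets absent from diet_table: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list:
        return list(self.samples["sample_id"])

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def covariate(self, name: str) -> pd.Series:
        """Per-sample values of a diet covariate, indexed by sample id."""
        per_diet = self.diet_table.loc[name]
        out = self.samples["diet"].map(per_diet)
        out.index = self.samples["sample_id"]
        out.name = name
        return out.astype(float)

    def factor(self, name: str) -> pd.Series:
        """A categorical design column (steer/period/diet) by sample id."""
        out = self.samples[name].copy()
        out.index = self.samples["sample_id"]
        return out

    def subset(self, mask) -> "StudyDesign":
        """Restrict to samples where ``mask`` (aligned boolean) is true."""
        sub = self.samples.loc[np.asarray(mask, bool)].reset_index(drop=True)
        return StudyDesign(sub, self.diet_table)


def builtin_diet_table() -> pd.DataFrame:
    """Diet composition covariates of the four treatments.

    Returns a covariate-by-diet table; rows are named nutrient measures
    (``tdn``, ``adf``, ``ndf``, ``crude_protein``, ``zn``, ...).
    """
    return pd.DataFrame(_DIET_TABLE_ROWS, index=_DIET_IDS).T.astype(float)


def builtin_design() -> StudyDesign:
    """The 5-steer x 4-period crossover layout of the feeding trial."""
    rows = []
    for steer, diets in _BUILTIN_LAYOUT.items():
        for period, diet in enumerate(diets, start=1):
            rows.append(
                {
                    "sample_id": f"{steer}.P{period}",
                    "steer": steer,
                    "period": period,
                    "diet": diet,
                }
            )
    return StudyDesign(pd.DataFrame(rows), builtin_diet_table())


def make_crossover_design(
    n_steers: int,
    n_periods: int,
    diet_ids: Sequence[str],
    seed: int = 0,
    diet_table: pd.DataFrame | None = None,
) -> StudyDesign:
    """Randomize a row-column crossover design.

    Each steer receives ``n_periods`` diets without repetition.  When
    ``n_steers == n_periods == len(diet_ids)`` the layout is a Latin
    square (each diet once per steer and once per period); additional
    steers receive independent random diet orders.

    Parameters
    ----------
    n_steers, n_periods : int
        Layout dimensions; requires ``n_steers >= n_periods``.
    diet_ids : sequence of str
        Treatment identifiers; must have length ``n_periods``.
    seed : int
        Seeds the randomization.
    diet_table : pd.DataFrame, optional
        Covariate table; defaults to the built-in diet composition when
        the diet ids match it, otherwise a single constant covariate.

    Raises
    ------
    DesignError
        If the layout is impossible (more periods than diets, fewer
        steers than periods).
    """
    diet_ids = list(diet_ids)
    if len(diet_ids) != n_periods:
        raise DesignError(
            f"need exactly one diet per period: {len(diet_ids)} diets, "
            f"{n_periods} periods"
        )
    if n_steers < n_periods:
        raise DesignError("need at least as many steers as periods")
    if len(set(diet_ids)) != len(diet_ids):
        raise DesignError("diet ids must be unique")

    rng = np.random.default_rng(seed)
    d = n_periods
    # Cyclic Latin square with rows/columns/symbols shuffled: stays Latin.
    base = (np.arange(d)[:, None] + np.arange(d)[None, :]) % d
    base = base[rng.permutation(d)][:, rng.permutation(d)]
    symbols = rng.permutation(d)
    square = symbols[base]

    rows = []
    for i in range(n_steers):
        if i < d:
            order = [diet_ids[square[i, j]] for j in range(d)]
        else:
            order = [diet_ids[k] for k in rng.permutation(d)]
        steer = f"st{i + 1}"
        for period, diet in enumerate(order, start=1):
            rows.append(
                {
                    "sample_id": f"{steer}.P{period}",
                    "steer": steer,
                    "period": period,
                    "diet": diet,
                }
            )

    if diet_table is None:
        builtin = builtin_diet_table()
        if set(diet_ids) <= set(builtin.columns):
            diet_table = builtin[diet_ids]
        else:
            # Fabricate a monotone energy-like covariate so downstream
            # code always finds a numeric gradient.
            vals = np.linspace(70.0, 85.0, len(diet_ids))
            diet_table = pd.DataFrame({d_: [v] for d_, v in zip(diet_ids, vals)}, index=["tdn"])
    return StudyDesign(pd.DataFrame(rows), diet_table)
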