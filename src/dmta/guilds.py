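"""Dietary compositions, guild assignment and the per-parameter screen.

Extant taxa (crocodilians, monitor lizards, bats, ...) with known diets form
the comparative framework.  Each taxon carries a volumetric dietary
composition; guild labels group consumers by prey "intractability":
carnivores (tetrapod consumers), piscivores, harder / softer / softest
invertebrate consumers, and omnivores (plant plus animal matter).

The statistical screen selects, guild-blind to everything but the labels,
the texture parameters that differ significantly between guilds: per
parameter a Levene test (median-centred) chooses classical versus Welch
ANOVA, raw P values are corrected across parameters by Benjamini–Hochberg
at FDR 0.05, and significant parameters get Tukey HSD (Tukey–Kramer for
unequal n) pairwise comparisons, which need no further correction.
Texture values are log10-transformed first; Ssk is excluded because it
takes negative values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GUILDS", "DietaryComposition", "Specimen", "GuildRules",
    "ParameterScreenResult", "assign_guild", "log_transform_parameters",
    "screen_parameters", "bh_adjust", "ranked_profile_test",
]

GUILDS = ("carnivore", "piscivore", "harder_invertebrate",
          "softer_invertebrate", "softest_invertebrate", "omnivore")

_PREY_TO_GUILD = {
    "tetrapods": "carnivore",
    "fish": "piscivore",
    "harder_invertebrates": "harder_invertebrate",
    "softer_invertebrates": "softer_invertebrate",
    "softest_invertebrates": "softest_invertebrate",
}

_TOL = 1e-9


@dataclass(frozen=True)
class DietaryComposition:
    """Volumetric diet proportions for one taxon (fractions of diet volume)."""

    taxon: str
    tetrapods: float = 0.0
    fish: float = 0.0
    harder_invertebrates: float = 0.0
    softer_invertebrates: float = 0.0
    softest_invertebrates: float = 0.0
    plants: float = 0.0
    generalism: float | None = None

    def __post_init__(self):
        for name in ("tetrapods", "fish", "harder_invertebrates",
                     "softer_invertebrates", "softest_invertebrates", "plants"):
            v = getattr(self, name)
            if not (-_TOL <= v <= 1 + _TOL):
                raise ValueError(f"{self.taxon}: proportion {name}={v} outside [0, 1]")
        if self.total() > 1 + _TOL:
            raise ValueError(f"{self.taxon}: proportions sum to {self.total():.4f} > 1")

    @property
    def total_vertebrates(self) -> float:
        return self.tetrapods + self.fish

    @property
    def total_invertebrates(self) -> float:
        return (self.harder_invertebrates + self.softer_invertebrates
                + self.softest_invertebrates)

    def total(self) -> float:
        return self.total_vertebrates + self.total_invertebrates + self.plants

    def as_dict(self) -> dict:
        return {
            "taxon": self.taxon,
            "tetrapods": self.tetrapods,
            "fish": self.fish,
            "total_vertebrates": self.total_vertebrates,
            "harder_invertebrates": self.harder_invertebrates,
            "softer_invertebrates": self.softer_invertebrates,
            "softest_invertebrates": self.softest_invertebrates,
            "total_invertebrates": self.total_invertebrates,
            "plants": self.plants,
        }


@dataclass(frozen=True)
class Specimen:
    """One sampled tooth surface with metadata."""

    specimen_id: str
    taxon: str
    guild: str = "unknown"
    jaw_length_cm: float | None = None
    collection: str | None = None
    ontogeny_note: str | None = None

    def __post_init__(self):
        if self.guild != "unknown" and self.guild not in GUILDS:
            raise ValueError(f"{self.specimen_id}: unknown guild {self.guild!r}")
        if self.jaw_length_cm is not None and self.jaw_length_cm <= 0:
            raise ValueError(f"{self.specimen_id}: jaw length must be positive")

    @property
    def is_fossil(self) -> bool:
        return self.guild == "unknown"


@dataclass(frozen=True)
class GuildRules:
    """Thresholds turning a composition into a guild label.

    ``omnivore_plant_min``: plant fraction at/above which a mixed
    plant+animal diet is an omnivore.  ``dominance_min``: minimum share of
    identified diet volume the winning prey category must reach.
    """

    omnivore_plant_min: float = 0.10
    dominance_min: float = 0.50


def assign_guild(diet: DietaryComposition, rules: GuildRules = GuildRules()) -> str:
    """Deterministically map a dietary composition to its guild.

    Plant plus animal matter above the plant threshold → omnivore;
    otherwise the dominant prey category names the guild.  Ties raise,
    listing the tied guilds; an all-zero composition raises.
    """
    total = diet.total()
    if total <= _TOL:
        raise ValueError(f"{diet.taxon}: all-zero dietary composition")
    animal = diet.total_vertebrates + diet.total_invertebrates
    if diet.plants >= rules.omnivore_plant_min and animal > _TOL:
        return "omnivore"
    if diet.plants / total > 1 - _TOL:
        return "omnivore"  # pure plant consumer is still a plant-eating omnivore here
    prey = {cat: getattr(diet, cat) for cat in _PREY_TO_GUILD}
    best = max(prey.values())
    winners = [cat for cat, v in prey.items() if abs(v - best) <= _TOL]
    if len(winners) > 1:
        tied = ", ".join(sorted(_PREY_TO_GUILD[c] for c in winners))
        raise ValueError(f"{diet.taxon}: tie between guilds ({tied}); resolve manually")
    winner = winners[0]
    if best / (animal + diet.plants) < rules.dominance_min - _TOL:
        raise ValueError(
            f"{diet.taxon}: no category reaches the {rules.dominance_min:.0%} "
            "dominance threshold; resolve manually")
    return _PREY_TO_GUILD[winner]


# ---------------------------------------------------------------------------
# Parameter screen
# ---------------------------------------------------------------------------

def log_transform_parameters(table: pd.DataFrame, base: float = 10.0) -> pd.DataFrame:
    """Log-transform a specimen × parameter table, dropping Ssk.

    Ssk is excluded because skewness takes negative values and cannot be
    log-transformed.  Any remaining non-positive value raises, naming the
    specimen and parameter.  Column order is otherwise preserved.
    """
    out = table.drop(columns=[c for c in table.columns if c == "Ssk"])
    numeric = out.select_dtypes(include=[np.number]).columns
    for col in numeric:
        bad = out.index[out[col] <= 0]
        if len(bad):
            raise ValueError(
                f"non-positive value for parameter {col!r} in specimen {bad[0]!r}; "
                "cannot log-transform")
    out = out.copy()
    out[numeric] = np.log(out[numeric].to_numpy(dtype=float)) / np.log(base)
    return out


def bh_adjust(pvals: Sequence[float], fdr: float = 0.05):
    """Benjamini–Hochberg step-up procedure.

    Returns ``(flags, adjusted)``: ``flags[i]`` is True when p_i falls at or
    below the largest rank i with p_(i) ≤ i·fdr/m; adjusted values are the
    usual monotone step-up q-values.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = (np.arange(1, m + 1) / m) * fdr
    passing = np.nonzero(ranked <= thresholds)[0]
    flags = np.zeros(m, dtype=bool)
    if passing.size:
        flags[order[: passing[-1] + 1]] = True
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.clip(adj, 0, 1)
    adjusted = np.empty(m)
    adjusted[order] = adj
    return flags, adjusted


@dataclass(frozen=True)
class ParameterScreenResult:
    """Outcome of the per-parameter guild screen."""

    table: pd.DataFrame            # parameter, test, F, p_raw, p_adjusted, significant
    tukey: dict                    # parameter -> DataFrame of pairwise Tukey HSD P values
    untestable: tuple = ()
    fdr: float = 0.05

    @property
    def significant(self) -> list:
        return list(self.table.loc[self.table["significant"], "parameter"])

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def screen_parameters(table: pd.DataFrame, guilds: Sequence[str],
                      fdr: float = 0.05, levene_alpha: float = 0.05,
                      pairwise: bool = True) -> ParameterScreenResult:
    """Screen each texture parameter for differences between dietary guilds.

    For every numeric column: a median-centred Levene test at
    ``levene_alpha`` selects classical ANOVA (homogeneous variances) or
    Welch ANOVA; raw P values across all testable parameters form one
    Benjamini–Hochberg family at ``fdr``; parameters flagged significant
    get Tukey HSD pairwise guild comparisons (Tukey–Kramer under unequal
    n), with no further correction.  ``pairwise=False`` skips the Tukey
    stage (e.g. in simulation studies that only need the flags).

    Parameters constant within every guild are untestable and excluded
    from the B–H family.  Requires ≥ 2 guilds with ≥ 2 specimens each.
    """
    guilds = np.asarray(list(guilds))
    if len(guilds) != len(table):
        raise ValueError("guilds must align with table rows")
    labels, counts = np.unique(guilds, return_counts=True)
    if len(labels) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 guilds each with >= 2 specimens")
    params = list(table.select_dtypes(include=[np.number]).columns)

    rows = []
    untestable = []
    groups_by_param = {}
    for p in params:
        groups = [table[p].to_numpy(dtype=float)[guilds == g] for g in labels]
        if all(np.ptp(g) == 0 for g in groups):
            untestable.append(p)
            continue
        groups_by_param[p] = groups
        lev_p = stats.levene(*groups, center="median").pvalue
        equal_var = bool(lev_p > levene_alpha)
        res = stats.f_oneway(*groups, equal_var=equal_var)
        rows.append({"parameter": p,
                     "test": "anova" if equal_var else "welch_anova",
                     "levene_p": float(lev_p),
                     "F": float(res.statistic),
                     "p_raw": float(res.pvalue)})
    out = pd.DataFrame(rows, columns=["parameter", "test", "levene_p", "F", "p_raw"])
    flags, adjusted = bh_adjust(out["p_raw"], fdr) if len(out) else (np.zeros(0, bool), np.zeros(0))
    out["p_adjusted"] = adjusted
    out["significant"] = flags

    tukey = {}
    if pairwise:
        for p in out.loc[out["significant"], "parameter"]:
            res = stats.tukey_hsd(*groups_by_param[p])
            tukey[p] = pd.DataFrame(res.pvalue, index=labels, columns=labels)
    return ParameterScreenResult(table=out, tukey=tukey,
                                 untestable=tuple(untestable), fdr=fdr)


def ranked_profile_test(means_a: Sequence[float], means_b: Sequence[float]):
    """Matched-pairs t-test comparing two guilds' parameter-mean profiles.

    Both profiles must cover the identical parameter list (length ≥ 3).
    Returns ``(t, df, P)``; antisymmetric under argument swap.  A constant
    pairwise difference (zero variance) returns ``(nan, df, nan)`` with a
    degenerate flag via ``numpy.nan`` rather than an infinite statistic.
    """
    a = np.asarray(list(means_a), dtype=float)
    b = np.asarray(list(means_b), dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D and cover the same parameters")
    if a.size < 3:
        raise ValueError("profiles must contain at least 3 parameters")
    d = a - b
    df = d.size - 1
    if np.ptp(d) == 0:
        if np.all(d == 0):
            return 0.0, df, 1.0
        return float("nan"), df, float("nan")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), df, float(res.pvalue)
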