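"""Generative model of segment-level endophyte colonization.

Emulates the survey design: n_species fungal taxa, 3 seasons x 6 sites x
3 tissues, r replicate samples per cell, a fixed number of incubated
segments per replicate.  Each segment is independently colonized by each
species with probability

    p(species i, cell) = p_i * e_season * e_site * e_tissue * interactions

where the species base probabilities p_i follow a geometric ranked-
abundance series (a few core dominant taxa plus a tail of rare ones) and
the multiplicative factor effects control the cell means that the
factorial ANOVA acts on.  Probabilities are clamped to [0, 1] and clamp
events counted.

Defaults are calibrated loosely to the study's observed scale: 24
species, 45 segments per replicate, triplicates (135 segments per cell),
and a base rate giving roughly 1.9e3 isolates over the whole survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .anova import anova_three_way
from .data import (
    SEASONS,
    SITES,
    TISSUES,
    AbundanceVector,
    CFMatrix,
    SegmentDesign,
)
from .diversity import shannon, simpson_dominance, species_richness

__all__ = ["CommunityModel", "simulate_isolations", "recovery_experiment", "load_model"]

_RNG_ALGORITHM = "numpy.random.Generator(PCG64)"


def _unit_effects(levels) -> dict:
    return {lv: 1.0 for lv in levels}


@dataclass
class CommunityModel:
    """Parameters of the colonization simulator.

    abundance_shape is the geometric-series ratio k in (0, 1): species i
    (0-based rank) has base probability proportional to k**i, scaled so
    the mean per-segment per-species probability equals base_rate.
    Factor effects multiply that probability for every observation in the
    matching level; interaction_effects maps frozenset({(factor, level),
    (factor, level)}) to an extra multiplier.
    """

    n_species: int = 24
    abundance_shape: float = 0.8
    base_rate: float = 0.011
    season_effects: dict = field(default_factory=lambda: _unit_effects(SEASONS))
    site_effects: dict = field(default_factory=lambda: _unit_effects(SITES))
    tissue_effects: dict = field(default_factory=lambda: _unit_effects(TISSUES))
    interaction_effects: dict = field(default_factory=dict)
    design: SegmentDesign = field(default_factory=SegmentDesign)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.abundance_shape < 1:
            raise ValueError("abundance_shape k must lie in (0, 1)")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if self.base_rate < 0:
            raise ValueError("base_rate must be nonnegative")
        for eff in (self.season_effects, self.site_effects, self.tissue_effects):
            if any(v <= 0 for v in eff.values()):
                raise ValueError("factor effect multipliers must be > 0")

    def species_probabilities(self) -> np.ndarray:
        """Per-segment base colonization probability of each species.

        Geometric series normalized so the species mean is base_rate.
        """
        k = self.abundance_shape
        w = k ** np.arange(self.n_species)
        return self.base_rate * w / w.mean()

    def relative_abundances(self) -> np.ndarray:
        """Expected relative abundance of each species (the generating SAD)."""
        p = self.species_probabilities()
        return p / p.sum() if p.sum() > 0 else np.full(self.n_species, 1 / self.n_species)

    def true_shannon(self) -> float:
        pi = self.relative_abundances()
        pi = pi[pi > 0]
        return float(-np.sum(pi * np.log(pi)))

    def true_simpson(self) -> float:
        pi = self.relative_abundances()
        return float(np.sum(pi**2))

    def metadata(self) -> dict:
        """Generating parameters, for attachment to simulated outputs."""
        meta = asdict(self)
        meta["interaction_effects"] = {
            " & ".join(f"{f}:{lv}" for f, lv in sorted(key)): v
            for key, v in self.interaction_effects.items()
        }
        meta["rng"] = _RNG_ALGORITHM
        return meta


def _cell_probability(model: CommunityModel, season: str, site: int, tissue: str) -> float:
    mult = (
        model.season_effects.get(season, 1.0)
        * model.site_effects.get(site, 1.0)
        * model.tissue_effects.get(tissue, 1.0)
    )
    for key, v in model.interaction_effects.items():
        pairs = set(key)
        if pairs <= {("season", season), ("site", site), ("tissue", tissue)}:
            mult *= v
    return mult


@dataclass
class SimulationResult:
    """Replicate-level counts plus the derived CF matrix and provenance."""

    replicates: pd.DataFrame  # species, season, site, tissue, replicate, count
    cf: CFMatrix
    clamped: int  # number of (species, cell) probabilities clamped to [0, 1]
    metadata: dict

    @property
    def species(self) -> list[str]:
        return list(dict.fromkeys(self.replicates["species"]))

    def response_per_replicate(self) -> pd.DataFrame:
        """Total isolates per replicate sample: the survey's ANOVA response."""
        out = (
            self.replicates.groupby(["season", "site", "tissue", "replicate"], sort=False)[
                "count"
            ]
            .sum()
            .reset_index()
            .rename(columns={"count": "response"})
        )
        return out

    def pooled_abundance(self) -> AbundanceVector:
        pooled = self.replicates.groupby("species", sort=False)["count"].sum()
        return AbundanceVector({sp: int(c) for sp, c in pooled.items()}, label="pooled")


def simulate_isolations(model: CommunityModel) -> SimulationResult:
    """Draw one full synthetic survey under the model.

    For every cell, replicate, segment and species, occupancy is an
    independent Bernoulli draw; counts per (species, replicate) are the
    binomial aggregates.  CF per (species, cell) is the colonized
    fraction of the cell's segments, in percent.  Same seed, same output.
    """
    rng = np.random.default_rng(model.seed)
    p_base = model.species_probabilities()
    design = model.design
    r, n_seg = design.replicates_per_cell, design.segments_per_replicate

    species = [f"SP{i + 1:02d}" for i in range(model.n_species)]
    rows = []
    clamped = 0
    for season in SEASONS:
        for site in SITES:
            for tissue in TISSUES:
                p_cell = p_base * _cell_probability(model, season, site, tissue)
                n_clamp = int(np.sum((p_cell > 1.0) | (p_cell < 0.0)))
                clamped += n_clamp
                p_cell = np.clip(p_cell, 0.0, 1.0)
                # shape (r, n_species): segment successes per replicate
                counts = rng.binomial(n_seg, p_cell, size=(r, model.n_species))
                for rep in range(1, r + 1):
                    for i, sp in enumerate(species):
                        rows.append((sp, season, site, tissue, rep, counts[rep - 1, i]))
    replicates = pd.DataFrame(
        rows, columns=["species", "season", "site", "tissue", "replicate", "count"]
    )

    per_cell = (
        replicates.groupby(["species", "season", "site", "tissue"], sort=False)["count"]
        .sum()
        .reset_index()
    )
    per_cell["cf"] = per_cell["count"] * 100 / design.n_total
    cf = CFMatrix(
        per_cell[["species", "season", "site", "tissue", "cf"]], species=species
    )
    return SimulationResult(replicates, cf, clamped, model.metadata())


def recovery_experiment(
    model: CommunityModel, n_sims: int, alpha: float = 0.05
) -> pd.DataFrame:
    """Repeated simulation + re-analysis: how well do the estimators recover?

    Each simulation records observed richness against n_species, the
    Shannon/Simpson indices of the pooled observed counts against the
    generating abundance distribution's values, and the ANOVA p-value and
    alpha-level rejection indicator for every source.  Simulation s uses
    seed ``model.seed + s`` so runs are reproducible yet independent.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    records = []
    for s in range(n_sims):
        m = CommunityModel(**{**_model_kwargs(model), "seed": model.seed + s})
        sim = simulate_isolations(m)
        pooled = sim.pooled_abundance()
        rec: dict[str, object] = {
            "sim": s,
            "richness_observed": species_richness(pooled),
            "n_species": m.n_species,
        }
        if pooled.total > 0 and species_richness(pooled) > 0:
            rec["shannon_observed"] = shannon(pooled)
            rec["simpson_observed"] = simpson_dominance(pooled)
        else:
            rec["shannon_observed"] = np.nan
            rec["simpson_observed"] = np.nan
        rec["shannon_true"] = m.true_shannon()
        rec["simpson_true"] = m.true_simpson()
        table = anova_three_way(sim.response_per_replicate())
        for src in table.sources:
            if src in ("error", "total"):
                continue
            p = table[src]["p"]
            key = src.replace(" x ", "_x_")
            rec[f"p_{key}"] = p
            rec[f"reject_{key}"] = bool(p < alpha)
        records.append(rec)
    return pd.DataFrame(records)


def _model_kwargs(model: CommunityModel) -> dict:
    return {
        "n_species": model.n_species,
        "abundance_shape": model.abundance_shape,
        "base_rate": model.base_rate,
        "season_effects": dict(model.season_effects),
        "site_effects": dict(model.site_effects),
        "tissue_effects": dict(model.tissue_effects),
        "interaction_effects": dict(model.interaction_effects),
        "design": model.design,
        "seed": model.seed,
    }


def load_model(path: str | Path) -> CommunityModel:
    """Build a CommunityModel from a YAML/JSON configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    kwargs = dict(cfg)
    if "design" in kwargs:
        kwargs["design"] = SegmentDesign(**kwargs["design"])
    if "site_effects" in kwargs:
        kwargs["site_effects"] = {int(k): float(v) for k, v in kwargs["site_effects"].items()}
    if "interaction_effects" in kwargs:
        parsed = {}
        for key, v in kwargs["interaction_effects"].items():
            pairs = []
            for part in key.split("&"):
                factor, level = part.strip().split(":")
                pairs.append((factor, int(level) if factor == "site" else level))
            parsed[frozenset(pairs)] = float(v)
        kwargs["interaction_effects"] = parsed
    return CommunityModel(**kwargs)
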