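"""Seeded synthetic cohorts and character matrices.

The cohort generator emulates the statistical structure of the comparative
study design: fourteen species in three groups, seventeen individuals
(two lambeosaurine species contribute ontogenetic series), long
closed-ended lambeosaurine airways versus shorter open-ended airways in the
other two groups, and one focal early-branching taxon with three open
airflow pathways whose lengths are fixed to values back-calculated from its
reported fundamentals.

Airway lengths are drawn log-normally (lengths are positive and
right-skewed across taxa).  The default medians and log-scale spreads are
chosen so that the closed-tube fundamentals of adult lambeosaurines span
roughly 58–154 Hz and the open-tube fundamentals of the other groups
roughly 400–900 Hz, i.e. the group separation the analysis is meant to
detect.  Immature individuals get the species' adult length scaled by a
stage factor (incipiently developed crests mean shorter airways).

The matrix generator evolves binary characters by single state changes on
the edges of a random true tree, with extra (homoplastic) changes injected
at a configurable probability, for exercising the parsimony machinery.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .airway import AirwayPathway, build_pathway
from .characters import CharacterMatrix
from .errors import ConfigError
from .parsimony import tree_from_newick
from .resonance import DEFAULT_HARMONICS, DEFAULT_SPEED_OF_SOUND

#: Focal-taxon airway lengths (m), back-calculated from its reported
#: open-tube fundamentals (~672, ~272 and ~415 Hz at v = 343 m/s).
FOCAL_LENGTHS_M = {
    "primary": 0.2549,
    "anterodorsal": 0.6305,
    "anteroventral": 0.4135,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-cohort generator settings.

    Defaults encode the reference design: 5 lambeosaurine species (two with
    ontogenetic series), 4 saurolophines, 5 non-hadrosaurid hadrosauroids
    including the focal taxon — 14 species, 17 individuals.
    """

    seed: int = 1
    v: float = DEFAULT_SPEED_OF_SOUND
    K: int = DEFAULT_HARMONICS
    #: lambeosaurine median-chamber length distribution (closed tubes);
    #: median ≈ √(0.557 × 1.478) m so f₁ spans ≈58–154 Hz
    lamb_n_species: int = 5
    lamb_median_m: float = 0.91
    lamb_log_sd: float = 0.25
    #: lateral diverticulum drawn slightly shorter than the median chamber,
    #: so its fundamental is slightly higher
    diverticulum_ratio: float = 0.9
    #: open primary-airway distribution shared by saurolophines and
    #: non-hadrosaurid hadrosauroids; median ≈ √(0.19 × 0.43) m
    saur_n_species: int = 4
    nonhadro_n_species: int = 5
    open_median_m: float = 0.286
    open_log_sd: float = 0.18
    #: ontogenetic series: extra immature individuals for the first
    #: lambeosaurine species (juvenile + subadult) and the second (juvenile)
    ontogeny: tuple[tuple[str, ...], ...] = (("juvenile", "subadult"),
                                             ("juvenile",))
    juvenile_factor: float = 0.5
    subadult_factor: float = 0.8
    include_focal: bool = True
    focal_taxon: str = "Qianjiangsaurus"
    focal_stage: str = "subadult"
    focal_lengths_m: tuple[tuple[str, float], ...] = tuple(
        sorted(FOCAL_LENGTHS_M.items())
    )

    def __post_init__(self) -> None:
        if self.lamb_n_species < 1 or self.saur_n_species < 1 \
                or self.nonhadro_n_species < 1:
            raise ConfigError("every group needs at least one species")
        for name in ("lamb_median_m", "open_median_m"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("lamb_log_sd", "open_log_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0 < self.diverticulum_ratio <= 1:
            raise ConfigError("diverticulum_ratio must be in (0, 1]")
        for name in ("juvenile_factor", "subadult_factor"):
            if not 0 < getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in (0, 1]")
        if len(self.ontogeny) > self.lamb_n_species:
            raise ConfigError("more ontogenetic series than lambeosaurine species")
        if self.include_focal and self.nonhadro_n_species < 1:
            raise ConfigError("focal taxon requires a non-hadrosaurid slot")


def _stage_factor(stage: str, config: CohortConfig) -> float:
    return {"adult": 1.0, "subadult": config.subadult_factor,
            "juvenile": config.juvenile_factor}[stage]


def simulate_cohort(config: CohortConfig = CohortConfig()
                    ) -> list[AirwayPathway]:
    """Deterministic (seeded) synthetic airway cohort, one row per
    (individual, route)."""
    rng = np.random.default_rng(config.seed)
    pathways: list[AirwayPathway] = []

    # lambeosaurines: closed median chamber + slightly shorter diverticulum
    for i in range(config.lamb_n_species):
        taxon = f"Lambeosaurine_{chr(65 + i)}"
        adult_len = config.lamb_median_m * float(
            np.exp(rng.normal(0.0, config.lamb_log_sd)))
        stages = ("adult",) + (config.ontogeny[i]
                               if i < len(config.ontogeny) else ())
        for stage in stages:
            L = adult_len * _stage_factor(stage, config)
            sid = f"{taxon}_{stage}"
            pathways.append(build_pathway(
                sid, taxon, "lambeosaurine", stage, "median_chamber",
                "closed", length_m=L))
            pathways.append(build_pathway(
                sid, taxon, "lambeosaurine", stage, "lateral_diverticulum",
                "closed", length_m=L * config.diverticulum_ratio))

    # saurolophines: one open primary airway per adult individual
    for i in range(config.saur_n_species):
        taxon = f"Saurolophine_{chr(65 + i)}"
        L = config.open_median_m * float(
            np.exp(rng.normal(0.0, config.open_log_sd)))
        pathways.append(build_pathway(
            f"{taxon}_adult", taxon, "saurolophine", "adult", "primary",
            "open", length_m=L))

    # non-hadrosaurid hadrosauroids; last slot is the focal taxon
    n_plain = config.nonhadro_n_species - (1 if config.include_focal else 0)
    for i in range(n_plain):
        taxon = f"Hadrosauroid_{chr(65 + i)}"
        L = config.open_median_m * float(
            np.exp(rng.normal(0.0, config.open_log_sd)))
        pathways.append(build_pathway(
            f"{taxon}_adult", taxon, "non_hadrosaurid", "adult", "primary",
            "open", length_m=L))
    if config.include_focal:
        for route, L in config.focal_lengths_m:
            pathways.append(build_pathway(
                f"{config.focal_taxon}_{config.focal_stage}",
                config.focal_taxon, "non_hadrosaurid", config.focal_stage,
                route, "open", length_m=L))
    return pathways


def cohort_summary(pathways: Sequence[AirwayPathway]) -> dict:
    individuals = {p.specimen_id for p in pathways}
    species = {p.taxon for p in pathways}
    return {
        "n_individuals": len(individuals),
        "n_species": len(species),
        "n_airways": len(pathways),
    }


# ---------------------------------------------------------------------------
# Character-matrix simulation

@dataclass(frozen=True)
class MatrixSimConfig:
    """Binary-character simulator on a random true tree."""

    n_taxa: int = 6
    n_char: int = 20
    homoplasy_p: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ConfigError("need at least 4 taxa")
        if self.n_char < 1:
            raise ConfigError("need at least one character")
        if not 0.0 <= self.homoplasy_p <= 1.0:
            raise ConfigError("homoplasy probability must be in [0, 1]")


def _random_topology(taxa: Sequence[str], rng: np.random.Generator) -> str:
    """Random unrooted binary topology (basal trifurcation), as Newick."""
    nodes = list(taxa)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(f"({a},{b})")
    return "(" + ",".join(nodes) + ");"


def simulate_matrix(config: MatrixSimConfig = MatrixSimConfig()
                    ) -> tuple[CharacterMatrix, dendropy.Tree]:
    """Synthetic matrix plus its true tree.

    Each character is born on one random edge of the true tree (state 1 in
    that clade).  With probability ``homoplasy_p`` an additional random
    clade is flipped, injecting convergence or reversal.  With
    ``homoplasy_p = 0`` the matrix is perfectly congruent with the true
    tree (its length there equals the ensemble minimum, CI = 1).
    """
    rng = np.random.default_rng(config.seed)
    taxa = tuple(f"T{i}" for i in range(config.n_taxa))
    newick = _random_topology(taxa, rng)
    tree = tree_from_newick(newick)
    # clades = leaf sets below each non-root node (proper, non-full subsets)
    all_leaves = frozenset(taxa)
    clades = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 0 < len(below) < len(all_leaves):
            clades.append(below)
    cols = []
    for _ in range(config.n_char):
        derived = clades[int(rng.integers(len(clades)))]
        states = {t: ("1" if t in derived else "0") for t in taxa}
        if rng.random() < config.homoplasy_p:
            flip = clades[int(rng.integers(len(clades)))]
            for t in flip:
                states[t] = "1" if states[t] == "0" else "0"
        cols.append(states)
    cells = tuple(
        tuple(frozenset({col[t]}) for col in cols) for t in taxa
    )
    matrix = CharacterMatrix(taxa=taxa, cells=cells)
    return matrix, tree
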