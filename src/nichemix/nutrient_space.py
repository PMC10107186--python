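"""Nutritional (N-space) transformation of diet posteriors.

Each posterior diet vector is pushed through fixed per-source macronutrient
compositions: the % of nutrient Y in the diet at draw i is
sum_t %Y_t * P_{i,t}. Uncertainty therefore propagates solely from the
proportion posterior; prey compositions are treated as fixed literature
means (a per-source SD hook exists but is off by default).

Nutritional-geometry (right-angled mixture triangle) coordinates plot %P on
x and %L on y; %W = 100 - x - y increases toward the origin.

The nutritional c-index is the mean paired cosine similarity between an
individual's and the population's (pP, pL, pW) draws, rescaled so that 0
corresponds to the minimum cosine similarity attainable between two diets
built from the sources in the model (compositions lie in the convex hull of
the source compositions, so the minimum is attained at a pair of hull
vertices).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .mixing_model import DietPosterior, c_index
from .niche_compare import beta_glm
from .tables_io import NutrientComposition

__all__ = [
    "NutrientPosterior",
    "diet_to_nutrients",
    "ngf_coordinates",
    "min_attainable_cosine",
    "c_index_nutrients",
    "ngf_plot",
    "pn_relationship",
]


@dataclass(frozen=True)
class NutrientPosterior:
    """Draws of dietary %P, %L, %W (wet mass) plus the per-draw P:L ratio."""

    entity: str
    draws: np.ndarray  # (D, 3) columns (pP, pL, pW)

    def __post_init__(self) -> None:
        if self.draws.ndim != 2 or self.draws.shape[1] != 3:
            raise ValueError("draws must be (D, 3) in (pP, pL, pW) order")

    @property
    def pl_ratio(self) -> np.ndarray:
        return self.draws[:, 0] / self.draws[:, 1]

    @property
    def mean(self) -> np.ndarray:
        return self.draws.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        return self.draws.std(axis=0, ddof=1)


def diet_to_nutrients(diet: DietPosterior, nutrients) -> NutrientPosterior:
    """Transform a diet posterior into a nutrient-intake posterior.

    ``nutrients`` is a sequence of :class:`NutrientComposition` aligned with
    the diet's source order (or a dict keyed by the diet's source labels).
    """
    if isinstance(nutrients, dict):
        try:
            comps = [nutrients[lab] for lab in diet.source_labels]
        except KeyError as exc:
            raise ValueError(f"missing composition for source {exc.args[0]!r}") from exc
    else:
        comps = list(nutrients)
    if len(comps) != diet.draws.shape[1]:
        raise ValueError("one composition required per source")
    if any(c is None for c in comps):
        raise ValueError("missing composition for a source")
    M = np.stack([c.as_array() for c in comps])  # (K, 3) rows (pP, pL, pW)
    return NutrientPosterior(diet.entity, diet.draws @ M)


def ngf_coordinates(nc: NutrientComposition) -> tuple[float, float]:
    """Right-angled mixture-triangle coordinates (x=%P, y=%L); %W is implicit."""
    return nc.pP, nc.pL


def min_attainable_cosine(source_compositions) -> float:
    """Minimum cosine similarity between any two attainable diet compositions.

    The attainable set is the convex hull of the source compositions; cosine
    similarity along segments into the hull is quasi-concave in each
    argument, so the minimum over the hull x hull product is attained at a
    vertex pair. Searched exhaustively over source pairs (verified against a
    grid oracle in the test suite).
    """
    M = np.stack([c.as_array() for c in source_compositions])
    if len(M) < 2:
        return 1.0
    best = 1.0
    for i, j in combinations(range(len(M)), 2):
        a, b = M[i], M[j]
        cs = float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        best = min(best, cs)
    return best


def c_index_nutrients(
    ind: NutrientPosterior, pop: NutrientPosterior, source_compositions
) -> float:
    """Rescaled mean cosine similarity of nutrient draws, in [0, 1].

    raw similarities are compressed by the narrow attainable composition
    range, so the index is rescaled as (raw - c_min) / (1 - c_min) with
    c_min the minimum attainable cosine; if all sources share one
    composition (c_min = 1) there is no nutritional contrast and the index
    is defined as 1.
    """
    raw = c_index(ind.draws, pop.draws)
    c_min = min_attainable_cosine(source_compositions)
    if c_min >= 1.0 - 1e-12:
        return 1.0
    return float(np.clip((raw - c_min) / (1.0 - c_min), 0.0, 1.0))


def ngf_plot(
    posteriors: dict,
    source_compositions,
    path,
    reference_point: tuple | None = None,
):
    """Right-angled mixture-triangle plot of diets and sources (SVG/PNG).

    ``posteriors`` maps entity -> :class:`NutrientPosterior` (plotted as
    posterior mean +- SD bars); sources appear as triangles at their fixed
    compositions. %P is on x, %L on y; %W increases toward the origin. An
    optional externally supplied ``reference_point`` (pP, pL) — e.g. a
    stomach-content estimate — is overlaid as an open circle.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    M = np.stack([c.as_array() for c in source_compositions])
    ax.scatter(M[:, 0], M[:, 1], marker="^", s=60, color="tab:green", label="sources")
    for ent, npst in posteriors.items():
        m, sd = npst.mean, npst.sd
        is_pop = ent == "population"
        ax.errorbar(
            m[0], m[1], xerr=sd[0], yerr=sd[1],
            fmt="o" if is_pop else "s",
            color="black" if is_pop else "tab:grey",
            ms=7 if is_pop else 4,
            capsize=2,
            label="population" if is_pop else None,
        )
    if reference_point is not None:
        ax.scatter(*reference_point, facecolors="none", edgecolors="black", s=70)
    ax.set_xlabel("% protein (wet mass)")
    ax.set_ylabel("% lipid (wet mass)")
    ax.set_title("% water implicit (increases toward origin)", fontsize=9)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def pn_relationship(c_prey, c_nut):
    """Beta GLM of nutritional similarity (response) on prey-use similarity.

    Returns the fit summary from :func:`nichemix.niche_compare.beta_glm`
    with the slope estimate, SE, z and p for the c-index_prey coefficient.
    """
    c_prey = np.asarray(c_prey, dtype=float)
    X = np.column_stack([np.ones_like(c_prey), c_prey])
    return beta_glm(np.asarray(c_nut, dtype=float), X, names=["intercept", "c_index_prey"])
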