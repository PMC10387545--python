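"""Truth-tagged simulation of polytomous Rasch response data.

The generator draws responses from the partial credit model and can inject
controlled violations of each model requirement:

* **local item dependency** — with probability ``d`` the dependent item's
  response is replaced by the source item's response (clipped to its own
  range), the simplest mechanism that produces a positive residual
  correlation of tunable size;
* **DIF** — a per-group additive shift of the item location (uniform DIF) or
  a per-group multiplier on the latent trait for that item (non-uniform);
* **multidimensionality** — items are assigned to latent dimensions whose
  person locations are multivariate normal with correlation ``r``;
* **off-targeting** — via the trait mean relative to the (mean-zero) items;
* **missingness** — missing completely at random at a fixed cell rate.

Every draw is tagged: the returned truth record carries the generating
person locations, item parameters and injected violations, so downstream
detectors can be scored against ground truth.

:func:`whodas_like_fixture` builds a synthetic stand-in for a typical
post-stroke disability assessment: 188 persons, 11 five-category items in
six conceptual domains, within-domain dependency, two correlated components
(physical vs cognitive/social) and covariates (grouped age, gender,
education including an illiterate category, grouped illness duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimate import ResponseMatrix
from .model_core import ItemParameters, category_probability

__all__ = [
    "LIDLink",
    "DIFSpec",
    "SimulationDesign",
    "simulate_responses",
    "standard_items",
    "whodas_like_fixture",
    "WHODAS_DOMAINS",
    "WHODAS_COMPONENTS",
]


@dataclass
class LIDLink:
    source: str
    dependent: str
    d: float  # dependence probability in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.d <= 1.0:
            raise ValueError("dependence probability d must be in [0, 1]")


@dataclass
class DIFSpec:
    item: str
    factor: str
    #: per-group location shift in logits (uniform) or trait multiplier (non-uniform)
    group_effects: dict[str, float] = field(default_factory=dict)
    kind: str = "uniform"  # uniform | non_uniform

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "non_uniform"):
            raise ValueError("DIF kind must be uniform or non_uniform")


@dataclass
class SimulationDesign:
    n_persons: int
    items: list[ItemParameters]
    theta_mean: float = 0.0
    theta_sd: float = 1.0
    lid_links: list[LIDLink] = field(default_factory=list)
    dif_specs: list[DIFSpec] = field(default_factory=list)
    #: covariate table (one row per person) used to evaluate DIF groups
    covariates: pd.DataFrame | None = None
    #: item_id -> dimension index; None means unidimensional
    dimension_map: dict[str, int] | None = None
    dim_correlation: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons <= 0:
            raise ValueError("n_persons must be positive")
        if not self.items:
            raise ValueError("item list is empty")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")
        if not -1.0 <= self.dim_correlation <= 1.0:
            raise ValueError("dim_correlation must be in [-1, 1]")
        ids = {it.item_id for it in self.items}
        if self.dimension_map is not None and set(self.dimension_map) != ids:
            raise ValueError("dimension_map must assign every item exactly once")


def _draw_thetas(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    """(n_persons, n_dims) latent locations."""
    if design.dimension_map is None:
        dims = 1
    else:
        dims = len(set(design.dimension_map.values()))
    if dims == 1:
        z = rng.standard_normal((design.n_persons, 1))
    else:
        r = design.dim_correlation
        cov = np.full((dims, dims), r, dtype=float)
        np.fill_diagonal(cov, 1.0)
        chol = np.linalg.cholesky(cov)
        z = rng.standard_normal((design.n_persons, dims)) @ chol.T
    return design.theta_mean + design.theta_sd * z


def simulate_responses(design: SimulationDesign):
    """Draw a response matrix under the design; returns (matrix, truth record).

    The same seed yields a bit-identical matrix.  Responses are drawn from
    the partial credit model at each person's (dimension-specific,
    DIF-shifted) location, then dependency links are applied in order, then
    MCAR missingness.
    """
    rng = np.random.default_rng(design.seed)
    items = design.items
    ids = [it.item_id for it in items]
    dim_of = {iid: 0 for iid in ids} if design.dimension_map is None else design.dimension_map
    dim_index = {d: i for i, d in enumerate(sorted(set(dim_of.values())))}
    thetas = _draw_thetas(design, rng)

    dif_by_item: dict[str, list[DIFSpec]] = {}
    for spec in design.dif_specs:
        if design.covariates is None or spec.factor not in design.covariates.columns:
            raise ValueError(f"DIF factor {spec.factor!r} not in covariates")
        dif_by_item.setdefault(spec.item, []).append(spec)

    n = design.n_persons
    values = np.empty((n, len(items)), dtype=float)
    for j, it in enumerate(items):
        th = thetas[:, dim_index[dim_of[it.item_id]]].copy()
        for spec in dif_by_item.get(it.item_id, []):
            groups = design.covariates[spec.factor].astype(str).to_numpy()
            for g, eff in spec.group_effects.items():
                mask = groups == str(g)
                if spec.kind == "uniform":
                    th[mask] = th[mask] - eff  # harder item == lower effective trait
                else:
                    th[mask] = th[mask] * eff
        p = category_probability(th, it)
        u = rng.random(n)
        values[:, j] = (u[:, None] > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1)

    col = {iid: j for j, iid in enumerate(ids)}
    for link in design.lid_links:
        copy = rng.random(n) < link.d
        src = values[:, col[link.source]]
        mx = items[col[link.dependent]].max_score
        values[copy, col[link.dependent]] = np.clip(src[copy], 0, mx)

    if design.missing_rate > 0:
        drop = rng.random(values.shape) < design.missing_rate
        # never blank a person's entire row
        full_blank = drop.all(axis=1)
        drop[full_blank, rng.integers(0, len(items), size=int(full_blank.sum()))] = False
        values[drop] = np.nan

    rm = ResponseMatrix(
        values, np.array([it.max_score for it in items]),
        [f"P{k+1:04d}" for k in range(n)], ids,
    )
    truth = {
        "theta": thetas,
        "dimension_of": dict(dim_of),
        "items": items,
        "lid_links": list(design.lid_links),
        "dif_specs": list(design.dif_specs),
        "seed": design.seed,
    }
    return rm, truth


def standard_items(
    n_items: int = 11, n_categories: int = 5, span: float = 2.0,
    spacing_jitter: float = 0.3, seed: int = 0,
) -> list[ItemParameters]:
    """A realistic PCM item bank: locations evenly spanning ±``span`` logits,
    per-item threshold spacings jittered so the partial credit form holds."""
    rng = np.random.default_rng(seed)
    locs = np.linspace(-span, span, n_items)
    m = n_categories - 1
    base = np.linspace(-1.5, 1.5, m)
    items = []
    for i, loc in enumerate(locs):
        off = base + rng.normal(0, spacing_jitter, m)
        off -= off.mean()
        items.append(ItemParameters(f"I{i+1:02d}", loc + np.sort(off)))
    return items


# --------------------------------------------------------------------------
# The worked-example stand-in fixture (synthetic)
# --------------------------------------------------------------------------

WHODAS_DOMAINS: dict[str, list[str]] = {
    "understanding": ["D1.1", "D1.4"],
    "getting_around": ["D2.1", "D2.5"],
    "self_care": ["D3.1", "D3.2"],
    "getting_along": ["D4.1", "D4.2"],
    "life_activities": ["D5.1"],  # the work/school partner item is structurally missing
    "participation": ["D6.1", "D6.5"],
}

WHODAS_COMPONENTS: dict[str, str] = {
    "D1.1": "cognitive_social", "D1.4": "cognitive_social",
    "D2.1": "physical", "D2.5": "physical",
    "D3.1": "physical", "D3.2": "physical",
    "D4.1": "cognitive_social", "D4.2": "cognitive_social",
    "D5.1": "physical",
    "D6.1": "cognitive_social", "D6.5": "cognitive_social",
}

# item locations loosely follow the difficulty ordering of a disability
# instrument in a stroke inpatient sample (household tasks easiest to
# endorse, concentration hardest)
_FIXTURE_LOCATIONS = {
    "D1.1": 0.94, "D1.4": 0.36, "D2.1": -0.06, "D2.5": -0.47, "D3.1": -0.31,
    "D3.2": 0.01, "D4.1": 0.47, "D4.2": 0.79, "D5.1": -1.07, "D6.1": -0.36,
    "D6.5": -0.29,
}


def whodas_like_fixture(seed: int = 0):
    """Synthetic 188 x 11 disability-assessment data set with covariates.

    Emulates the structure of a stroke-inpatient administration of a
    12-item WHO disability schedule with the work item removed: 11
    five-category items in six domains, strong within-domain dependency
    (d=0.5 between domain partners, plus a household-to-self-care link),
    two latent components (physical vs cognitive/social, r=0.7 — correlated
    but separable, so that within-component dependency surfaces once the
    domains are testletized), and a
    modest uniform education DIF on the concentration/learning items for
    the illiterate group.  Returns (responses, covariates, truth).
    """
    rng = np.random.default_rng(seed)
    n = 188
    items = []
    base = np.linspace(-1.4, 1.4, 4)
    for iid, loc in _FIXTURE_LOCATIONS.items():
        off = base + rng.normal(0, 0.35, 4)
        items.append(ItemParameters(iid, loc + (off - off.mean())))

    covariates = pd.DataFrame({
        "age_group": rng.choice(["<65", "65+"], n, p=[0.55, 0.45]),
        "gender": rng.choice(["male", "female"], n, p=[0.537, 0.463]),
        "education": rng.choice(["illiterate", "primary", "secondary+"], n,
                                p=[0.2, 0.45, 0.35]),
        "duration_group": rng.choice(["<30d", "30d+"], n, p=[0.5, 0.5]),
    }, index=pd.Index([f"P{k+1:04d}" for k in range(n)], name="person_id"))

    design = SimulationDesign(
        n_persons=n,
        items=items,
        theta_mean=0.0,
        theta_sd=1.0,
        lid_links=[
            LIDLink("D1.1", "D1.4", 0.5),
            LIDLink("D2.1", "D2.5", 0.5),
            LIDLink("D3.1", "D3.2", 0.5),
            LIDLink("D4.1", "D4.2", 0.5),
            LIDLink("D6.1", "D6.5", 0.5),
            LIDLink("D3.1", "D5.1", 0.4),
        ],
        dif_specs=[
            DIFSpec("D1.1", "education", {"illiterate": 0.4}),
            DIFSpec("D1.4", "education", {"illiterate": 0.4}),
        ],
        covariates=covariates,
        dimension_map=dict(WHODAS_COMPONENTS),
        dim_correlation=0.7,
        missing_rate=0.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    rm, truth = simulate_responses(design)
    truth["domains"] = {k: list(v) for k, v in WHODAS_DOMAINS.items()}
    truth["components"] = dict(WHODAS_COMPONENTS)
    return rm, covariates, truth
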