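"""Penalized B-spline (P-spline) influence model.

The influence function f(d) gives a binding site's additive contribution
to a gene's (centered) log expression as a function of its signed distance
d from the TSS.  f is expressed in a cubic B-spline basis,

    f(d) = sum_k c_k B_k(d),

and each enhancer contributes alpha_j * f(d_j) additively, so a gene's
prediction is linear in the coefficients c:

    yhat_i = sum_k c_k b_{i,k},   b_{i,k} = sum_j alpha_j B_k(d_j).

The coefficients minimize the penalized mean squared error

    F(c) = (1/N) ||y - B c||^2 + sigma * c' D c,

where D = Delta' Delta is the discrete second-difference penalty (the
standard P-spline approximation to the integrated squared second
derivative) and sigma >= 0 trades data fit against smoothness.  The
minimizer solves the normal equations (B'B/N + sigma D) c = B'y/N exactly;
no iteration is involved.

The basal-expression term is handled by mean-centering responses upstream
rather than by fitting an intercept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.interpolate import BSpline

from .genome_model import GeneBindingProfile, ProfileEntry

__all__ = [
    "SplineBasis",
    "InfluenceModel",
    "SingularModelError",
    "build_basis",
    "design_features",
    "design_matrix",
    "penalty_matrix",
    "penalized_objective",
    "fit_coefficients",
    "fit_influence_model",
    "predict_absolute",
    "predict_differential",
    "influence_curve",
    "write_model",
    "read_model",
]

MODEL_SCHEMA_VERSION = "reginfluence-model/1"

DEFAULT_SIGMA_GRID = np.logspace(-4, 2, 7)


class SingularModelError(np.linalg.LinAlgError):
    """The penalized normal equations are singular; increase sigma."""


@dataclass(frozen=True)
class SplineBasis:
    """Cubic (by default) B-spline basis over a signed-distance domain.

    ``knots`` has ``n_basis + degree + 1`` entries with the boundary knot
    repeated ``degree + 1`` times at each end; interior knots are uniform.
    The basis functions form a partition of unity on the domain and all
    evaluate to 0 outside it.
    """

    degree: int
    d_min: float
    d_max: float
    n_basis: int
    knots: np.ndarray

    def evaluate(self, x) -> np.ndarray:
        """Matrix of basis-function values, shape (len(x), n_basis)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.zeros((x.size, self.n_basis))
        inside = (x >= self.d_min) & (x <= self.d_max)
        if inside.any():
            dm = BSpline.design_matrix(
                x[inside], self.knots, self.degree, extrapolate=False
            )
            out[inside] = dm.toarray()
        return out


def build_basis(
    d_min: float, d_max: float, n_basis: int = 20, degree: int = 3
) -> SplineBasis:
    """Uniform-knot B-spline basis of ``n_basis`` functions on [d_min, d_max]."""
    if d_min >= d_max:
        raise ValueError("d_min must be < d_max")
    if n_basis < degree + 1:
        raise ValueError(f"n_basis must be >= degree + 1 = {degree + 1}")
    n_interior = n_basis - degree - 1
    interior = np.linspace(d_min, d_max, n_interior + 2)[1:-1]
    knots = np.concatenate(
        [np.full(degree + 1, d_min), interior, np.full(degree + 1, d_max)]
    )
    return SplineBasis(degree, float(d_min), float(d_max), n_basis, knots)


def design_features(
    profile: GeneBindingProfile,
    basis: SplineBasis,
    value: str = "distance",
    regulator_weights: dict[str, float] | None = None,
    combine: str = "mean",
) -> np.ndarray:
    """Per-gene feature vector b_k = sum_j alpha_j B_k(x_j).

    ``value`` selects the basis argument: the signed distance (position
    model) or the site conservation score (conservation model).  An empty
    profile yields the zero vector.
    """
    if not profile.entries:
        return np.zeros(basis.n_basis)
    if value == "distance":
        x = np.array([e.signed_distance for e in profile.entries], dtype=float)
    elif value == "conservation":
        missing = [e.site_id for e in profile.entries if e.conservation is None]
        if missing:
            raise ValueError(f"entries missing conservation score: {missing[:5]}")
        x = np.array([e.conservation for e in profile.entries], dtype=float)
    else:
        raise ValueError(f"unknown value kind {value!r}")
    alpha = np.array(
        [e.alpha * _site_multiplier(e, regulator_weights, combine) for e in profile.entries]
    )
    return alpha @ basis.evaluate(x)


def _site_multiplier(
    entry: ProfileEntry, weights: dict[str, float] | None, combine: str
) -> float:
    """Regulator-identity multiplier for one site (1.0 when no weights)."""
    if not weights or not entry.regulators:
        return 1.0
    vals = [weights.get(r, 1.0) for r in entry.regulators]
    if combine == "mean":
        return float(np.mean(vals))
    if combine == "product":
        return float(np.prod(vals))
    if combine == "max":
        return float(np.max(vals))
    raise ValueError(f"unknown combine rule {combine!r}")


def design_matrix(
    profiles: list[GeneBindingProfile],
    basis: SplineBasis,
    profiles_b: list[GeneBindingProfile] | None = None,
    value: str = "distance",
    regulator_weights: dict[str, float] | None = None,
    combine: str = "mean",
) -> np.ndarray:
    """Stack per-gene features; subtract tissue-b features if given (Δ model).

    All entries across all profiles are flattened into one basis
    evaluation, so building the matrix is a single vectorized pass.
    """
    if profiles_b is not None and len(profiles_b) != len(profiles):
        raise ValueError("profiles_a and profiles_b must align gene-for-gene")
    B = np.zeros((len(profiles), basis.n_basis))

    def _accumulate(plist, sign):
        gene_idx, xs, alphas = [], [], []
        for i, p in enumerate(plist):
            for e in p.entries:
                gene_idx.append(i)
                if value == "distance":
                    xs.append(float(e.signed_distance))
                elif value == "conservation":
                    if e.conservation is None:
                        raise ValueError(f"entry {e.site_id} missing conservation score")
                    xs.append(float(e.conservation))
                else:
                    raise ValueError(f"unknown value kind {value!r}")
                alphas.append(
                    e.alpha * sign * _site_multiplier(e, regulator_weights, combine)
                )
        if not xs:
            return
        E = basis.evaluate(np.asarray(xs))
        np.add.at(B, np.asarray(gene_idx), np.asarray(alphas)[:, None] * E)

    _accumulate(profiles, 1.0)
    if profiles_b is not None:
        _accumulate(profiles_b, -1.0)
    return B


def penalty_matrix(n_basis: int, order: int = 2) -> np.ndarray:
    """Difference-penalty matrix D = Delta' Delta on spline coefficients.

    For order 2 the null space is spanned by constant and linear
    coefficient sequences, so the penalty shrinks toward a straight line.
    """
    if order >= n_basis:
        raise ValueError(f"penalty order ({order}) must be < n_basis ({n_basis})")
    delta = np.diff(np.eye(n_basis), n=order, axis=0)
    return delta.T @ delta


def penalized_objective(
    B: np.ndarray, y: np.ndarray, c: np.ndarray, sigma: float, D: np.ndarray
) -> float:
    """(1/N)||y - Bc||^2 + sigma c'Dc."""
    resid = y - B @ c
    return float(resid @ resid / len(y) + sigma * c @ D @ c)


def fit_coefficients(
    B: np.ndarray, y: np.ndarray, sigma: float, D: np.ndarray
) -> np.ndarray:
    """Exact minimizer of the penalized MSE via the normal equations."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    n = len(y)
    if n < 1:
        raise ValueError("need at least one observation")
    A = B.T @ B / n + sigma * D
    rhs = B.T @ y / n
    try:
        cf = scipy.linalg.cho_factor(A)
        return scipy.linalg.cho_solve(cf, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularModelError(
            "penalized normal equations are singular; use a larger sigma or more data"
        ) from exc


@dataclass
class InfluenceModel:
    """A fitted influence function with its basis and regularization."""

    basis: SplineBasis
    coefficients: np.ndarray
    sigma: float
    penalty_order: int = 2
    regulator_weights: dict[str, float] | None = None
    combine: str = "mean"
    variant: str = "position"  # position | conservation

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.shape != (self.basis.n_basis,):
            raise ValueError("coefficient count must equal basis size")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.regulator_weights is not None and any(
            w <= 0 for w in self.regulator_weights.values()
        ):
            raise ValueError("regulator weights must be > 0")

    def influence(self, x) -> np.ndarray:
        """f evaluated at signed distances (or conservation scores)."""
        return self.basis.evaluate(x) @ self.coefficients

    def _features(self, profile: GeneBindingProfile) -> np.ndarray:
        value = "conservation" if self.variant == "conservation" else "distance"
        return design_features(
            profile, self.basis, value, self.regulator_weights, self.combine
        )

    def predict_profile(self, profile: GeneBindingProfile) -> float:
        return float(self._features(profile) @ self.coefficients)


def fit_influence_model(
    profiles: list[GeneBindingProfile],
    responses,
    basis: SplineBasis,
    sigma: float | str = "auto",
    profiles_b: list[GeneBindingProfile] | None = None,
    value: str = "distance",
    penalty_order: int = 2,
    regulator_weights: dict[str, float] | None = None,
    combine: str = "mean",
    sigma_grid=None,
    rng: np.random.Generator | None = None,
) -> InfluenceModel:
    """Fit the influence function to per-gene responses.

    With ``profiles_b`` given, the model predicts the log fold change
    between tissues a and b (features are differenced).  ``sigma='auto'``
    picks the regularization strength from ``sigma_grid`` by held-out MSE
    on an internal 2/3 - 1/3 split, then refits on all genes.
    """
    y = np.asarray(responses, dtype=float)
    B = design_matrix(profiles, basis, profiles_b, value, regulator_weights, combine)
    D = penalty_matrix(basis.n_basis, penalty_order)

    if sigma == "auto":
        grid = DEFAULT_SIGMA_GRID if sigma_grid is None else np.asarray(sigma_grid, float)
        sigma = _select_sigma(B, y, D, grid, rng)
    c = fit_coefficients(B, y, float(sigma), D)
    return InfluenceModel(
        basis=basis,
        coefficients=c,
        sigma=float(sigma),
        penalty_order=penalty_order,
        regulator_weights=regulator_weights,
        combine=combine,
        variant="conservation" if value == "conservation" else "position",
    )


def _select_sigma(B, y, D, grid, rng) -> float:
    """Grid search over sigma by MSE on one internal validation split."""
    rng = np.random.default_rng(0) if rng is None else rng
    n = len(y)
    if n < 3:
        return float(grid[0])
    perm = rng.permutation(n)
    n_train = int(round(n * 2 / 3))
    tr, va = perm[:n_train], perm[n_train:]
    best_sigma, best_mse = None, np.inf
    for s in grid:
        try:
            c = fit_coefficients(B[tr], y[tr], float(s), D)
        except SingularModelError:
            continue
        mse = float(np.mean((y[va] - B[va] @ c) ** 2))
        if mse < best_mse:
            best_sigma, best_mse = float(s), mse
    if best_sigma is None:
        raise SingularModelError("no sigma on the grid yields a solvable system")
    return best_sigma


def predict_absolute(model: InfluenceModel, profile: GeneBindingProfile) -> float:
    """Predicted centered log expression: sum_j alpha_j f(d_j); 0 if unbound."""
    return model.predict_profile(profile)


def predict_differential(
    model: InfluenceModel,
    profile_a: GeneBindingProfile,
    profile_b: GeneBindingProfile,
) -> float:
    """Predicted log fold change a vs b, assuming shared basal/degradation rates."""
    if profile_a.gene_id != profile_b.gene_id:
        raise ValueError(
            f"profiles are for different genes: {profile_a.gene_id} vs {profile_b.gene_id}"
        )
    return model.predict_profile(profile_a) - model.predict_profile(profile_b)


def influence_curve(model: InfluenceModel, grid) -> list[tuple[float, float]]:
    """f(d) sampled on a grid of signed distances."""
    vals = model.influence(grid)
    return [(float(d), float(v)) for d, v in zip(np.atleast_1d(grid), vals)]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_model(model: InfluenceModel, path) -> None:
    payload = {
        "schema": MODEL_SCHEMA_VERSION,
        "basis": {
            "degree": model.basis.degree,
            "d_min": model.basis.d_min,
            "d_max": model.basis.d_max,
            "n_basis": model.basis.n_basis,
            "knots": model.basis.knots.tolist(),
        },
        "coefficients": model.coefficients.tolist(),
        "sigma": model.sigma,
        "penalty_order": model.penalty_order,
        "regulator_weights": model.regulator_weights,
        "combine": model.combine,
        "variant": model.variant,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_model(path) -> InfluenceModel:
    with open(path) as fh:
        payload = json.load(fh)
    schema = payload.get("schema")
    if schema != MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema {schema!r}; expected {MODEL_SCHEMA_VERSION!r}"
        )
    b = payload["basis"]
    basis = SplineBasis(
        degree=b["degree"],
        d_min=b["d_min"],
        d_max=b["d_max"],
        n_basis=b["n_basis"],
        knots=np.asarray(b["knots"], dtype=float),
    )
    return InfluenceModel(
        basis=basis,
        coefficients=np.asarray(payload["coefficients"], dtype=float),
        sigma=payload["sigma"],
        penalty_order=payload["penalty_order"],
        regulator_weights=payload["regulator_weights"],
        combine=payload["combine"],
        variant=payload["variant"],
    )
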