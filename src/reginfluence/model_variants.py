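"""Competing and extended models: uniform weighting, conservation-based
weighting, per-regulator influence weights, and ChIP-affinity weighting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import scipy.optimize
import scipy.sparse

from .genome_model import GeneBindingProfile, ProfileEntry
from .influence_model import (
    InfluenceModel,
    SplineBasis,
    build_basis,
    fit_coefficients,
    fit_influence_model,
    penalized_objective,
    penalty_matrix,
)

__all__ = [
    "UniformModel",
    "RegulatorWeightFit",
    "fit_uniform",
    "fit_conservation_model",
    "fit_regulator_weights",
    "apply_affinity_weights",
]

MIN_WEIGHT = 1e-6


@dataclass
class UniformModel:
    """Every binding event contributes equally regardless of position.

    The prediction is ``weight * sum_j alpha_j`` over sites within the
    cutoff (a net, signed count in the differential model).
    """

    weight: float

    def predict_profile(self, profile: GeneBindingProfile) -> float:
        return self.weight * sum(e.alpha for e in profile.entries)


def _alpha_sum(profile: GeneBindingProfile) -> float:
    return sum(e.alpha for e in profile.entries)


def fit_uniform(
    profiles: list[GeneBindingProfile],
    responses,
    profiles_b: list[GeneBindingProfile] | None = None,
) -> UniformModel:
    """Least-squares site-count weight: w = <x, y> / <x, x>."""
    y = np.asarray(responses, dtype=float)
    x = np.array([_alpha_sum(p) for p in profiles])
    if profiles_b is not None:
        x = x - np.array([_alpha_sum(p) for p in profiles_b])
    denom = float(x @ x)
    w = float(x @ y) / denom if denom > 0 else 0.0
    return UniformModel(weight=w)


def fit_conservation_model(
    profiles: list[GeneBindingProfile],
    responses,
    basis: SplineBasis | None = None,
    sigma: float | str = "auto",
    profiles_b: list[GeneBindingProfile] | None = None,
    rng: np.random.Generator | None = None,
) -> InfluenceModel:
    """Influence as a function of site conservation instead of position.

    Identical spline machinery, but the basis is evaluated at each site's
    conservation score on [0, 1].
    """
    if basis is None:
        basis = build_basis(0.0, 1.0, n_basis=8)
    return fit_influence_model(
        profiles,
        responses,
        basis,
        sigma=sigma,
        profiles_b=profiles_b,
        value="conservation",
        rng=rng,
    )


@dataclass
class RegulatorWeightFit:
    """Result of the bilinear position-and-regulator fit."""

    model: InfluenceModel
    weights: dict[str, float]
    reference: str
    n_iter: int
    converged: bool
    objective_trace: list[float]


def fit_regulator_weights(
    profiles: list[GeneBindingProfile],
    responses,
    basis: SplineBasis,
    sigma: float,
    reference: str,
    profiles_b: list[GeneBindingProfile] | None = None,
    max_iter: int = 50,
    tol: float = 1e-9,
    combine: str = "mean",
) -> RegulatorWeightFit:
    """Alternating least squares on the bilinear position x regulator model.

    yhat_i = sum_j a_j alpha_j f(d_j), where a_j combines the weights of
    the regulators bound at site j (mean by default).  The reference
    regulator's weight is fixed at 1 throughout, which both resolves the
    scale ambiguity between weights and curve and keeps each half-step an
    exact minimization, so the objective trace is non-increasing by
    construction.  Steps alternate: (i) fix weights, solve the penalized
    spline coefficients exactly; (ii) fix the curve, solve the remaining
    weights by non-negative least squares (clamped to a small positive
    floor).  A candidate weight update is kept only if it does not
    increase the objective.
    """
    if combine != "mean":
        raise NotImplementedError(
            "alternating fit supports the 'mean' combination rule; "
            "other rules are available for prediction only"
        )
    y = np.asarray(responses, dtype=float)
    n_genes = len(profiles)
    if profiles_b is not None and len(profiles_b) != n_genes:
        raise ValueError("profiles_a and profiles_b must align gene-for-gene")

    # Flatten entries: one row per (gene, site) pair, sign -1 for tissue b.
    gene_idx, alphas, xs, reg_lists = [], [], [], []
    signs = []

    def _collect(plist, sign):
        for i, p in enumerate(plist):
            for e in p.entries:
                if not e.regulators:
                    raise ValueError(
                        f"site {e.site_id} has no regulator label; required for this fit"
                    )
                gene_idx.append(i)
                alphas.append(e.alpha * sign)
                xs.append(float(e.signed_distance))
                reg_lists.append(sorted(e.regulators))
                signs.append(sign)

    _collect(profiles, 1.0)
    if profiles_b is not None:
        _collect(profiles_b, -1.0)

    regulators = sorted({r for regs in reg_lists for r in regs})
    if reference not in regulators:
        raise ValueError(f"reference regulator {reference!r} not present in any site")
    r_index = {r: k for k, r in enumerate(regulators)}
    R = len(regulators)

    gene_idx = np.asarray(gene_idx)
    alphas = np.asarray(alphas)
    n_entries = len(xs)
    E = basis.evaluate(np.asarray(xs))  # (n_entries, P)
    # M[j, r] = 1/|regs_j| if regulator r bound at site j (mean combination)
    M = np.zeros((n_entries, R))
    for j, regs in enumerate(reg_lists):
        M[j, [r_index[r] for r in regs]] = 1.0 / len(regs)
    # Sparse gene-by-entry aggregator carrying alpha and tissue sign.
    A = scipy.sparse.csr_matrix(
        (alphas, (gene_idx, np.arange(n_entries))), shape=(n_genes, n_entries)
    )

    D = penalty_matrix(basis.n_basis)
    w = np.ones(R)
    ref_k = r_index[reference]
    others = [k for k in range(R) if k != ref_k]

    def _design(wvec):
        return A @ ((M @ wvec)[:, None] * E)

    trace: list[float] = []
    c = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        B = _design(w)
        c = fit_coefficients(B, y, sigma, D)
        f_now = penalized_objective(B, y, c, sigma, D)

        if others:
            # Per-entry curve contribution; gene-level design over weights.
            G = A @ ((E @ c)[:, None] * M)
            resid = y - G[:, ref_k]  # reference weight fixed at 1
            w_new = w.copy()
            sol, _ = scipy.optimize.nnls(G[:, others], resid)
            w_new[others] = np.maximum(sol, MIN_WEIGHT)
            f_new = penalized_objective(_design(w_new), y, c, sigma, D)
            if f_new <= f_now:
                w = w_new
                f_now = f_new

        trace.append(f_now)
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) <= tol * max(1.0, abs(trace[-2])):
            converged = True
            break

    weights = {r: float(w[r_index[r]]) for r in regulators}
    model = InfluenceModel(
        basis=basis,
        coefficients=c,
        sigma=float(sigma),
        regulator_weights=weights,
        combine=combine,
        variant="position",
    )
    return RegulatorWeightFit(
        model=model,
        weights=weights,
        reference=reference,
        n_iter=it,
        converged=converged,
        objective_trace=trace,
    )


def apply_affinity_weights(
    profiles: list[GeneBindingProfile], exponent: float = 1.0
) -> list[GeneBindingProfile]:
    """Up-weight sites with higher ChIP enrichment ratios.

    alpha_j <- alpha_j * (enrichment_j / median enrichment)^exponent, the
    median taken over the distinct sites appearing across the profiles.
    """
    seen: dict[str, float] = {}
    for p in profiles:
        for e in p.entries:
            if e.enrichment is None:
                raise ValueError(f"site {e.site_id} has no enrichment ratio")
            seen[e.site_id] = e.enrichment
    if not seen:
        return [GeneBindingProfile(p.gene_id, p.tissue, []) for p in profiles]
    median = float(np.median(list(seen.values())))
    out = []
    for p in profiles:
        entries = [
            replace(e, alpha=e.alpha * (e.enrichment / median) ** exponent)
            for e in p.entries
        ]
        out.append(GeneBindingProfile(p.gene_id, p.tissue, entries))
    return out
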