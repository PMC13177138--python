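"""Micelle-likeness analysis of a protein's hydrophobicity distribution.

A soluble globular protein ideally buries hydrophobic residues in its core
the way a spherical micelle does. That ideal is encoded as a centred 3D
Gaussian: the theoretical profile T assigns each residue the Gaussian
density at its position, maximal at the centre and vanishing at the
surface. The observed profile O aggregates distance-weighted pairwise
hydrophobic interactions between residues. Two scalars summarise the match:

* ``RD`` in [0, 1] — a Kullback–Leibler divergence ratio placing O between
  the Gaussian target T (RD = 0, perfect micelle-like ordering) and the
  uniform, unordered reference (RD = 1).
* ``K`` ≥ 0 — the environment parameter: the weight with which the target
  must be mixed toward its inverted counterpart TM (hydrophobicity exposed
  at the surface, as membranes or hydrophobic ligands would induce) to best
  explain O. The mixed target is the M distribution.

Residues whose observed hydrophobicity falls well below the theoretical
value (deficit) mark candidate binding cavities; residues well above
(excess) mark surface patches primed for protein–protein interaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, GeometryError, InputError
from .structure import StructureModel

__all__ = [
    "GaussParams", "HydroProfile", "FODResult",
    "orient_to_principal_axes", "fit_gaussian", "compute_T", "compute_O",
    "compute_TM", "compute_M", "kl_divergence", "compute_RD", "fit_K",
    "classify_residues", "analyze", "eliminate_and_recompute",
    "profile_frame", "plot_profile",
    "DEFAULT_CUTOFF", "DEFAULT_THRESHOLD_FRACTION",
]

DEFAULT_CUTOFF = 9.0  # Å; conventional inter-residue hydrophobic interaction range
DEFAULT_THRESHOLD_FRACTION = 0.5
_FLOOR = 1e-12  # divergence floor applied to targets with exact zeros

ACCORDANT = "accordant"
DEFICIT = "deficit"
EXCESS = "excess"


@dataclass(frozen=True)
class GaussParams:
    """Axis-aligned 3D Gaussian of the idealised hydrophobic core."""

    center: np.ndarray  # origin after centering
    sigma: np.ndarray   # one positive Å value per principal axis

    def __post_init__(self) -> None:
        sigma = np.asarray(self.sigma, dtype=float)
        if sigma.shape != (3,) or np.any(sigma <= 0):
            raise GeometryError(f"sigma must be three positive values, got {sigma!r}")
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))


@dataclass
class HydroProfile:
    """Per-residue normalized distributions for one chain.

    T is the theoretical micelle-like profile, O the observed one, TM the
    inverted (environment-dominated) profile and M the K-weighted mix of T
    toward TM actually used as the folding target.
    """

    n: int
    T: np.ndarray
    O: np.ndarray
    TM: np.ndarray
    M: np.ndarray
    K_used: float

    def __post_init__(self) -> None:
        for name in ("T", "O", "TM", "M"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (self.n,):
                raise InputError(f"{name} must have length n={self.n}")
            if np.any(v < 0):
                raise InputError(f"{name} has negative entries")
            if abs(v.sum() - 1.0) > 1e-9:
                raise InputError(f"{name} does not sum to 1 (sum={v.sum()!r})")
            setattr(self, name, v)
        if self.K_used < 0:
            raise InputError("K_used must be non-negative")


@dataclass
class FODResult:
    """Summary of one micelle-likeness analysis."""

    rd: float
    k_fit: float
    status: list[str]            # one of accordant / deficit / excess per residue
    eliminated: list[int]        # 0-based positions removed before recomputation
    scale_name: str
    profile: HydroProfile
    cutoff: float = DEFAULT_CUTOFF

    @property
    def n(self) -> int:
        return self.profile.n


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError(f"expected an (n, 3) point array, got shape {pts.shape}")
    return pts


def orient_to_principal_axes(points) -> np.ndarray:
    """Centre a point set and rotate it onto its covariance principal axes.

    The output is centred at the centroid with the largest-variance axis on
    x and the smallest on z, using a proper rotation (no reflection). The
    downstream Gaussian profile depends only on squared coordinates, so the
    per-axis sign ambiguity of the eigenvectors is harmless.
    """
    pts = _as_points(points)
    if len(pts) < 3:
        raise GeometryError("need at least 3 points to orient")
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0 or evals[1] <= 1e-10 * evals[0]:
        raise GeometryError("point set is degenerate (collinear or identical)")
    # deterministic sign convention, then enforce a proper rotation
    for k in range(3):
        if evecs[np.argmax(np.abs(evecs[:, k])), k] < 0:
            evecs[:, k] *= -1
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] *= -1
    return centred @ evecs


def fit_gaussian(oriented_points) -> GaussParams:
    """Per-axis Gaussian widths from the molecule's extent.

    σ along each principal axis is one third of the largest absolute
    coordinate on that axis, so the molecular surface sits near the 3σ
    shell where the density is effectively zero.
    """
    pts = _as_points(oriented_points)
    extent = np.abs(pts).max(axis=0)
    if np.any(extent == 0):
        raise GeometryError("zero extent along a principal axis")
    return GaussParams(center=np.zeros(3), sigma=extent / 3.0)


def compute_T(oriented_points, sigma=None) -> np.ndarray:
    """Theoretical micelle-like profile: normalized Gaussian density per residue.

    Ti ∝ exp(−xi²/2σx²)·exp(−yi²/2σy²)·exp(−zi²/2σz²). Points must already
    be centred and axis-aligned (see :func:`orient_to_principal_axes`).
    """
    pts = _as_points(oriented_points)
    if sigma is None:
        sigma = fit_gaussian(pts).sigma
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise GeometryError("sigma must be positive on every axis")
    raw = np.exp(-0.5 * np.sum((pts / sigma) ** 2, axis=1))
    return raw / raw.sum()


def contact_weight(u) -> np.ndarray:
    """Polynomial contact-decay g(u) = 1 − ½(7u² − 9u⁴ + 5u⁶ − u⁸) on [0, 1].

    g(0) = 1, g(1) = 0; zero beyond the cutoff.
    """
    u = np.asarray(u, dtype=float)
    g = 1.0 - 0.5 * (7 * u**2 - 9 * u**4 + 5 * u**6 - u**8)
    return np.where(u <= 1.0, g, 0.0)


def compute_O(points, h, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Observed profile from distance-weighted pairwise hydrophobic interactions.

    Oi ∝ Σ_{j≠i, rij ≤ cutoff} (hi + hj) · g(rij / cutoff). The self term is
    excluded. Raises :class:`ComputationError` when no residue pair interacts
    anywhere (all raw sums zero).
    """
    pts = _as_points(points)
    h = np.asarray(h, dtype=float)
    if len(h) != len(pts):
        raise InputError("points and hydrophobicities differ in length")
    if cutoff <= 0:
        raise InputError("cutoff must be positive")
    diff = pts[:, None, :] - pts[None, :, :]
    r = np.sqrt(np.sum(diff**2, axis=-1))
    g = contact_weight(r / cutoff)
    np.fill_diagonal(g, 0.0)
    raw = np.sum((h[:, None] + h[None, :]) * g, axis=1)
    total = raw.sum()
    if total <= 0:
        raise ComputationError("no inter-residue contacts within the cutoff")
    return raw / total


def compute_TM(T) -> np.ndarray:
    """Inverted profile: hydrophobicity exposed where the micelle ideal buries it.

    TMi ∝ max(T) − Ti, normalized. The argmax of T gets exactly zero.
    """
    T = np.asarray(T, dtype=float)
    raw = T.max() - T
    total = raw.sum()
    if total <= 0:
        raise ComputationError("T is constant; inverted profile undefined")
    return raw / total


def compute_M(T, TM, K: float) -> np.ndarray:
    """Environment-modified target: T mixed toward TM with weight K.

    Mi ∝ Ti + K·(TMi − Ti), clipped below at zero and renormalized.
    K = 0 returns T exactly; K = 1 returns TM.
    """
    if K < 0:
        raise InputError("K must be non-negative")
    T = np.asarray(T, dtype=float)
    if K == 0:
        return T.copy()
    TM = np.asarray(TM, dtype=float)
    raw = np.clip(T + K * (TM - T), 0.0, None)
    total = raw.sum()
    if total <= 0:
        raise ComputationError("M collapsed to zero after clipping")
    return raw / total


def kl_divergence(P, Q) -> float:
    """Kullback–Leibler divergence Σ Pi·log2(Pi/Qi) in bits, with 0·log 0 = 0."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise InputError("distributions differ in length")
    mask = P > 0
    if np.any(Q[mask] == 0):
        raise ComputationError("KL divergence undefined: P > 0 where Q = 0")
    val = float(np.sum(P[mask] * np.log2(P[mask] / Q[mask])))
    return max(val, 0.0)  # clamp tiny negative round-off


def compute_RD(O, T) -> float:
    """Relative-distance order parameter in [0, 1].

    RD = D(O‖T) / (D(O‖T) + D(O‖R)) with R uniform. RD = 0 means the
    observed profile matches the micelle-like target exactly; RD = 1 means
    it matches the unordered uniform reference. The degenerate 0/0 case
    (O = T = R) returns 0. Targets are floored at 1e-12 so exact zeros
    from the contact function cannot produce spurious infinities.
    """
    O = np.asarray(O, dtype=float)
    T = np.asarray(T, dtype=float)
    n = len(O)
    R = np.full(n, 1.0 / n)
    d_t = kl_divergence(O, np.maximum(T, _FLOOR))
    d_r = kl_divergence(O, R)
    denom = d_t + d_r
    if denom == 0.0:
        return 0.0
    return float(min(max(d_t / denom, 0.0), 1.0))


def _k_divergence(O, T, TM, K: float) -> float:
    return kl_divergence(O, np.maximum(compute_M(T, TM, K), _FLOOR))


def fit_K(O, T, TM, grid=None, refine_step: float = 0.001) -> float:
    """Grid-search the environment parameter K minimising D(O‖M(K)).

    The default coarse grid is 0 to 2 in steps of 0.01 (K is unbounded above
    in principle; pass a wider ``grid`` to search beyond 2), followed by one
    local refinement pass at ``refine_step`` around the coarse optimum. Ties
    break toward smaller K.
    """
    if grid is None:
        grid = np.arange(0.0, 2.0 + 1e-12, 0.01)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid < 0):
        raise InputError("K grid must be non-empty and non-negative")
    grid = np.sort(grid)

    def best_on(ks):
        best_k, best_d = None, np.inf
        for k in ks:
            d = _k_divergence(O, T, TM, float(k))
            if d < best_d:  # strict: ties keep the smaller K (ascending scan)
                best_k, best_d = float(k), d
        return best_k

    coarse = best_on(grid)
    step = np.min(np.diff(grid)) if grid.size > 1 else 0.0
    if step <= 0 or refine_step <= 0 or refine_step >= step:
        return coarse
    lo = max(coarse - step, 0.0)
    fine = np.arange(lo, coarse + step + refine_step / 2, refine_step)
    return best_on(fine)


def classify_residues(
    O, T, threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
) -> list[str]:
    """Label each residue accordant, deficit (Ti − Oi large) or excess (Oi − Ti large).

    The flagging threshold is ``threshold_fraction`` times the largest
    absolute deviation |Oi − Ti| in the chain, so flags mark the locally
    dominant departures rather than applying an absolute scale.
    """
    if not 0 < threshold_fraction <= 1:
        raise InputError("threshold_fraction must lie in (0, 1]")
    O = np.asarray(O, dtype=float)
    T = np.asarray(T, dtype=float)
    diff = T - O
    m = np.max(np.abs(diff)) if len(diff) else 0.0
    if m == 0.0:
        return [ACCORDANT] * len(diff)
    tau = threshold_fraction * m
    out = []
    for d in diff:
        if d > tau:
            out.append(DEFICIT)
        elif -d > tau:
            out.append(EXCESS)
        else:
            out.append(ACCORDANT)
    return out


def analyze(
    model: StructureModel,
    cutoff: float = DEFAULT_CUTOFF,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    k_grid=None,
) -> FODResult:
    """Full micelle-likeness analysis of a structure model.

    Orients the effective points, builds the T/O/TM profiles, computes RD,
    fits K, forms the M profile at the fitted K and classifies every residue.
    """
    if len(model) < 3:
        raise InputError("at least 3 residues are required")
    pts = orient_to_principal_axes(model.points)
    T = compute_T(pts)
    O = compute_O(pts, model.hydrophobicity, cutoff=cutoff)
    TM = compute_TM(T)
    rd = compute_RD(O, T)
    k = fit_K(O, T, TM, grid=k_grid)
    M = compute_M(T, TM, k)
    profile = HydroProfile(n=len(model), T=T, O=O, TM=TM, M=M, K_used=k)
    status = classify_residues(O, T, threshold_fraction)
    return FODResult(
        rd=rd, k_fit=k, status=status, eliminated=[],
        scale_name=model.scale_name, profile=profile, cutoff=cutoff,
    )


def eliminate_and_recompute(
    model: StructureModel,
    flagged: list[int],
    cutoff: float = DEFAULT_CUTOFF,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    k_grid=None,
) -> FODResult:
    """Remove flagged residues and redo the whole analysis on the remainder.

    Eliminating the residues that carry the local non-compliance tests
    whether the remaining chain is micelle-like (RD drops toward 0).
    ``flagged`` holds 0-based positions into ``model.residues``; they must
    leave at least 3 residues.
    """
    flagged_set = set(int(i) for i in flagged)
    if any(i < 0 or i >= len(model) for i in flagged_set):
        raise InputError("flagged positions out of range")
    keep = [i for i in range(len(model)) if i not in flagged_set]
    if len(keep) < 3:
        raise InputError("fewer than 3 residues would remain after elimination")
    result = analyze(
        model.subset(keep), cutoff=cutoff,
        threshold_fraction=threshold_fraction, k_grid=k_grid,
    )
    result.eliminated = sorted(flagged_set)
    return result


def profile_frame(model: StructureModel, result: FODResult):
    """Tidy per-residue table (chain, residue_index, residue_name, T, O, M, status)."""
    import pandas as pd

    residues = model.residues
    if result.eliminated:
        keep = [i for i in range(len(model)) if i not in set(result.eliminated)]
        residues = [model.residues[i] for i in keep]
    return pd.DataFrame(
        {
            "chain": [r.chain_id for r in residues],
            "residue_index": [r.residue_index for r in residues],
            "residue_name": [r.residue_name for r in residues],
            "T": result.profile.T,
            "O": result.profile.O,
            "M": result.profile.M,
            "status": result.status,
        }
    )


def plot_profile(result: FODResult, ax=None):
    """T/O/M line plot with deficit residues marked red and excess blue."""
    import matplotlib

    if ax is None:
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        _, ax = plt.subplots(figsize=(9, 4))
    x = np.arange(result.n)
    p = result.profile
    ax.plot(x, p.T, label="T (theoretical)", color="black")
    ax.plot(x, p.O, label="O (observed)", color="tab:green")
    ax.plot(x, p.M, label=f"M (K={result.k_fit:g})", color="tab:orange", ls="--")
    status = np.array(result.status)
    for label, color in ((DEFICIT, "red"), (EXCESS, "blue")):
        idx = np.nonzero(status == label)[0]
        if idx.size:
            ax.scatter(idx, p.O[idx], color=color, s=18, zorder=3, label=label)
    ax.set_xlabel("residue (chain order)")
    ax.set_ylabel("normalized hydrophobicity")
    ax.legend(loc="best", fontsize=8)
    ax.set_title(f"RD = {result.rd:.3f}, K = {result.k_fit:g}")
    return ax
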