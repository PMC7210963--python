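"""Approximately uniform sampling of the steady-state flux polytope.

The feasible set {v : S.v = 0, lb <= v <= ub} is a bounded polytope inside
the null space of S.  The sampler is coordinate hit-and-run in null-space
coordinates: from a feasible point, pick one null-space basis direction,
compute the feasible chord along it, and jump to a uniform point on that
chord.

Two practical refinements make the walk mix on realistic media: a
preparatory flux-variability pass identifies coordinates that are
numerically fixed (blocked or pinned reactions), and the null space is
taken of S augmented with unit rows for those coordinates — the affine
hull of the polytope — so every basis direction has a non-degenerate
chord.  The FVA vertex solutions are averaged into an interior-leaning
start point.

Every stored sample is audited against S.v = 0 (1e-6) and the box bounds;
seeded runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy import linalg, sparse

from . import lp
from .media import Medium
from .model import Model

DEFAULT_WARMUP = 1000
DEFAULT_THINNING = 100
_DIR_TOL = 1e-10
_FIXED_TOL = 1e-9


@dataclass
class SampleSet:
    reaction_ids: List[str]
    samples: np.ndarray  # n x |reactions|
    method: str = "hit-and-run"
    seed: int = 0
    warmup: int = DEFAULT_WARMUP
    thinning: int = DEFAULT_THINNING
    chains: int = 1

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    def column(self, rid: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(rid)]

    def summary(self) -> Dict[str, Tuple[float, float]]:
        """Per-reaction (mean, std) of the sampled fluxes."""
        means = self.samples.mean(axis=0)
        stds = self.samples.std(axis=0)
        return {
            rid: (float(means[j]), float(stds[j]))
            for j, rid in enumerate(self.reaction_ids)
        }


def _fva_warmup(S, lb, ub) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-coordinate FVA: (start point, per-coordinate min, max)."""
    n = S.shape[1]
    points = []
    lo = np.empty(n)
    hi = np.empty(n)
    for j in range(n):
        c = np.zeros(n)
        c[j] = 1.0
        for maximize in (False, True):
            sol = lp.solve_flux_lp(S, lb, ub, c, maximize=maximize)
            if sol.status != lp.STATUS_OPTIMAL:
                raise lp.SolverError(f"flux polytope is {sol.status}; cannot sample")
            points.append(sol.x)
            if maximize:
                hi[j] = sol.objective
            else:
                lo[j] = sol.objective
    return np.mean(points, axis=0), lo, hi


def sample_fluxes(
    model: Model,
    medium: Optional[Medium] = None,
    n: int = 1000,
    seed: int = 0,
    method: str = "hit-and-run",
    warmup: int = DEFAULT_WARMUP,
    thinning: int = DEFAULT_THINNING,
    extra_bounds: Optional[Mapping[str, Tuple[float, float]]] = None,
) -> SampleSet:
    if method != "hit-and-run":
        raise ValueError(f"unknown sampling method {method!r}")
    if n < 1:
        raise ValueError("n must be positive")
    from .flux import _assemble  # shared problem assembly

    S, lb, ub, index = _assemble(model, medium, extra_bounds)
    rng = np.random.default_rng(seed)
    v, fva_lo, fva_hi = _fva_warmup(S, lb, ub)
    rids = list(model.reactions)

    # affine hull: null space of S plus unit rows for pinned coordinates
    fixed = np.where(fva_hi - fva_lo < _FIXED_TOL)[0]
    A = S.toarray()
    if fixed.size:
        E = np.zeros((fixed.size, A.shape[1]))
        E[np.arange(fixed.size), fixed] = 1.0
        A = np.vstack([A, E])
        v[fixed] = (fva_lo[fixed] + fva_hi[fixed]) / 2.0
    N = linalg.null_space(A)
    if N.shape[1] == 0:
        samples = np.tile(v, (n, 1))
        _audit_rows(S, lb, ub, samples)
        return SampleSet(rids, samples, method, seed, warmup, thinning)

    d = N.shape[1]
    out = np.empty((n, S.shape[1]))
    stored = 0
    step = 0
    total = warmup + n * thinning
    while stored < n:
        # isotropic direction in null-space coordinates: mixes much faster
        # than axis-aligned basis directions in skewed polytopes
        w = rng.standard_normal(d)
        u = N @ (w / np.linalg.norm(w))
        active = np.abs(u) > _DIR_TOL
        to_upper = (ub - v)[active] / u[active]
        to_lower = (lb - v)[active] / u[active]
        alpha_hi = np.maximum(to_upper, to_lower).min()
        alpha_lo = np.minimum(to_upper, to_lower).max()
        if alpha_hi > alpha_lo:
            v = v + rng.uniform(alpha_lo, alpha_hi) * u
            np.clip(v, lb, ub, out=v)  # shave float fuzz at the faces
        step += 1
        if step > warmup and (step - warmup) % thinning == 0:
            out[stored] = v
            stored += 1
        if step > 100 * total:  # safety: should never trigger
            raise RuntimeError("hit-and-run failed to advance")
    _audit_rows(S, lb, ub, out)
    return SampleSet(rids, out, method, seed, warmup, thinning)


def _audit_rows(S, lb, ub, samples: np.ndarray) -> None:
    resid = np.abs(S @ samples.T)
    if resid.size and resid.max() > lp.STEADY_STATE_TOL:
        raise lp.SolverError(f"sample violates steady state by {resid.max():.3e}")
    if np.any(samples < lb - 1e-7) or np.any(samples > ub + 1e-7):
        raise lp.SolverError("sample violates flux bounds")
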