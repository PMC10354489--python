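"""Sloppy-parameter analysis of the linearized sensitivity system.

The deviation of the selected flows from steady state under a parameter
step ``L~`` costs ``Q = (1/tf) int_0^tf f~.T f~ dt = L~.T H L~`` where the
Hessian ``H = (1/tf) int_0^tf g(t) g(t).T dt`` is built from the unit-step
response matrix ``g(t)``.  Directions in parameter space along eigenvectors
of ``H`` with small eigenvalues barely move the output (sloppy
combinations); large eigenvalues mark stiff combinations.  For large ``tf``
the transient washes out and ``H -> Hinf = ginf ginf.T``, which for a single
output has rank one.

Reported sigma values are square roots of the Hessian eigenvalues, i.e. the
singular values of the response; the raw eigenvalues are also exposed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson

from .linear_analysis import LinearizedSensitivity, dc_gain, step_response

__all__ = [
    "SloppyDecomposition",
    "CostContour",
    "response_hessian",
    "steady_hessian",
    "decompose",
    "significant_modes",
    "cost_contour",
]

_DEFAULT_GRID = 2001


@dataclass
class SloppyDecomposition:
    """A response Hessian with its eigen-structure.

    ``sigma[i] = sqrt(eigenvalues[i])``; eigenvectors are orthonormal
    columns of ``V`` ordered by descending eigenvalue, each signed so its
    largest-magnitude component is positive.  ``tf`` is the integration
    horizon, ``math.inf`` for the steady-state Hessian.
    """

    H: np.ndarray
    tf: float
    eigenvalues: np.ndarray
    sigma: np.ndarray
    V: np.ndarray
    input_labels: list[str]
    output_labels: list[str]

    @property
    def n_params(self) -> int:
        return self.H.shape[0]

    def mode(self, i: int) -> tuple[float, np.ndarray]:
        return float(self.sigma[i]), self.V[:, i].copy()


def _fix_signs(V: np.ndarray) -> np.ndarray:
    V = V.copy()
    for i in range(V.shape[1]):
        col = V[:, i]
        k = int(np.argmax(np.abs(col)))
        if col[k] < 0:
            V[:, i] = -col
    return V


def decompose(H: np.ndarray, *, tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of a symmetric PSD matrix.

    Returns (sigma, V): sigma descending square roots of the eigenvalues,
    V orthonormal eigenvector columns with the largest-magnitude component
    of each taken positive.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("H must be square")
    if not np.allclose(H, H.T, atol=tol * max(1.0, np.abs(H).max())):
        raise ValueError("H must be symmetric")
    w, V = np.linalg.eigh((H + H.T) / 2)
    scale = max(1.0, w.max(initial=0.0))
    if w.min(initial=0.0) < -tol * scale:
        raise ValueError("H must be positive semi-definite")
    w = np.clip(w, 0.0, None)[::-1]
    V = _fix_signs(V[:, ::-1])
    return np.sqrt(w), V


def _decomposition(H, tf, lin, inputs_idx, outputs_idx) -> SloppyDecomposition:
    sigma, V = decompose(H)
    return SloppyDecomposition(
        H=H,
        tf=tf,
        eigenvalues=sigma**2,
        sigma=sigma,
        V=V,
        input_labels=[lin.input_labels[j] for j in inputs_idx],
        output_labels=[lin.output_labels[i] for i in outputs_idx],
    )


def _select(lin: LinearizedSensitivity, inputs, outputs):
    if inputs is None:
        inputs_idx = list(range(lin.n_inputs))
    else:
        inputs_idx = [i if isinstance(i, int) else lin.input_labels.index(i) for i in inputs]
    if outputs is None:
        outputs_idx = list(range(lin.n_outputs))
    else:
        outputs_idx = [
            i if isinstance(i, int) else lin.output_labels.index(i) for i in outputs
        ]
    return inputs_idx, outputs_idx


def response_hessian(
    lin: LinearizedSensitivity,
    tf: float,
    *,
    inputs=None,
    outputs=None,
    n_grid: int = _DEFAULT_GRID,
) -> SloppyDecomposition:
    """Finite-horizon Hessian H = (1/tf) int_0^tf g(t) g(t).T dt.

    The unit-step response is evaluated exactly (matrix exponential) on a
    dense uniform grid and integrated by composite Simpson quadrature;
    ``n_grid`` controls the resolution.
    """
    if not tf > 0:
        raise ValueError("tf must be positive")
    if not lin.is_stable:
        raise ValueError("response Hessian undefined for an unstable linearization")
    inputs_idx, outputs_idx = _select(lin, inputs, outputs)
    t = np.linspace(0.0, tf, n_grid)
    g = step_response(lin, t)[:, outputs_idx, :][:, :, inputs_idx]
    # integrand (n_t, n_in, n_in): g(t).T g(t) summed over outputs
    prod = np.einsum("tij,tik->tjk", g, g)
    H = simpson(prod, x=t, axis=0) / tf
    H = (H + H.transpose(1, 0)) / 2
    return _decomposition(H, tf, lin, inputs_idx, outputs_idx)


def steady_hessian(
    lin: LinearizedSensitivity, *, inputs=None, outputs=None
) -> SloppyDecomposition:
    """Steady-state Hessian Hinf = ginf.T ginf over the selected channels.

    For a single output this is the rank-one outer product of the DC-gain
    vector, so exactly one eigenvalue is nonzero and the leading eigenvector
    is ginf normalized.
    """
    inputs_idx, outputs_idx = _select(lin, inputs, outputs)
    g = dc_gain(lin)[np.ix_(outputs_idx, inputs_idx)]
    H = g.T @ g
    return _decomposition(H, math.inf, lin, inputs_idx, outputs_idx)


def significant_modes(
    decomp: SloppyDecomposition, eig_frac: float = 0.01, comp_frac: float = 0.10
) -> SloppyDecomposition:
    """Truncate a decomposition to its significant modes.

    Modes whose sigma falls below ``eig_frac`` times the largest sigma are
    dropped (sigma is the reported, square-rooted spectrum); within each
    kept eigenvector, components below ``comp_frac`` times the largest
    absolute component are zeroed (and not renormalized).
    """
    lam = decomp.eigenvalues
    sig = decomp.sigma
    if sig.size == 0 or sig[0] <= 0:
        keep = np.zeros(0, dtype=int)
    else:
        keep = np.nonzero(sig >= eig_frac * sig[0])[0]
    V = decomp.V[:, keep].copy()
    for i in range(V.shape[1]):
        col = V[:, i]
        col[np.abs(col) < comp_frac * np.abs(col).max()] = 0.0
    return SloppyDecomposition(
        H=decomp.H,
        tf=decomp.tf,
        eigenvalues=lam[keep],
        sigma=decomp.sigma[keep],
        V=V,
        input_labels=list(decomp.input_labels),
        output_labels=list(decomp.output_labels),
    )


@dataclass
class CostContour:
    """Sampled level set of the quadratic cost Q = L~.T H L~ in two parameters.

    Full-rank H gives a closed ellipse with semi-axes sqrt(level)/sigma_i
    along the eigenvectors; a rank-one H degenerates to two parallel lines
    perpendicular to the leading eigenvector.
    """

    level: float
    kind: str  # "ellipse" | "lines"
    points: np.ndarray  # (n, 2) for ellipse; (2, n, 2) for line pair
    input_labels: list[str]


def cost_contour(
    decomp_or_H, level: float = 1.0, *, n: int = 256, rank_tol: float = 1e-10
) -> CostContour:
    """Level set of the two-parameter quadratic cost.

    Accepts a :class:`SloppyDecomposition` or a bare 2x2 Hessian.
    """
    if isinstance(decomp_or_H, SloppyDecomposition):
        decomp = decomp_or_H
        labels = list(decomp.input_labels)
    else:
        H = np.asarray(decomp_or_H, dtype=float)
        sigma, V = decompose(H)
        decomp = SloppyDecomposition(
            H=H, tf=math.nan, eigenvalues=sigma**2, sigma=sigma, V=V,
            input_labels=["p1", "p2"], output_labels=[],
        )
        labels = list(decomp.input_labels)
    if decomp.n_params != 2:
        raise ValueError("cost contours are drawn in two-parameter space only")
    if level <= 0:
        raise ValueError("level must be positive")
    lam = decomp.eigenvalues
    if lam[0] <= 0:
        raise ValueError("zero Hessian has no finite contour")
    V = decomp.V
    if lam[1] > rank_tol * lam[0]:
        theta = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        semi = np.sqrt(level / lam)
        pts = (V * semi) @ np.vstack([np.cos(theta), np.sin(theta)])
        return CostContour(level, "ellipse", pts.T, labels)
    # rank one: |V1 . p| = sqrt(level/lam1), two lines along V2
    offset = math.sqrt(level / lam[0])
    s = np.linspace(-3 * offset - 1.0, 3 * offset + 1.0, n)
    lines = np.stack(
        [
            offset * V[:, 0][None, :] + s[:, None] * V[:, 1][None, :],
            -offset * V[:, 0][None, :] + s[:, None] * V[:, 1][None, :],
        ]
    )
    return CostContour(level, "lines", lines, labels)
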