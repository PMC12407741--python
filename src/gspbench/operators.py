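"""Graph shift operators and connectome harmonics.

A structural connectome (SC) is a symmetric, nonnegative, zero-diagonal
region-by-region matrix of white-matter connectivity estimates.  Four shift
operators can be built from it:

* ``L_U``  — unnormalized (combinatorial) Laplacian ``D - A``,
* ``L_N``  — symmetric normalized Laplacian ``D^{+1/2} L D^{+1/2}``,
* ``L_RW`` — random-walk Laplacian ``D^{+} L``,
* ``L_Q``  — modularity matrix ``A - k k^T / (2M)`` with ``M = sum(k)``
  (the default here; the textbook Newman form
  ``A - k k^T / M`` is available via ``convention="newman"``).

``D^{+}`` denotes the Moore-Penrose inverse of the degree matrix, so
zero-degree regions are handled gracefully.  Eigendecomposition of an
operator yields *connectome harmonics* (eigenmodes) with eigenvalues sorted
in ascending order.  Low-eigenvalue harmonics of a connected graph vary
smoothly over the connectome and resemble large-scale brain attributes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "PROPERTIES",
    "OPERATOR_KINDS",
    "StructuralConnectome",
    "ShiftOperator",
    "GraphSpectrum",
    "build_group_sc",
    "build_shift_operator",
    "eigendecompose",
]

PROPERTIES = ("NFD", "NF", "MFL", "MFA")
OPERATOR_KINDS = ("L_U", "L_N", "L_RW", "L_Q")

_SYMMETRIC_KINDS = ("L_U", "L_N", "L_Q")
_SYM_TOL = 1e-10


@dataclass
class StructuralConnectome:
    """Symmetric nonnegative edge-weight matrix for one edge property.

    Parameters
    ----------
    weights
        Square ``(R, R)`` matrix.  Must be symmetric within ``1e-10``
        (it is re-symmetrized as ``(A + A.T) / 2`` to guard against I/O
        round-off), nonnegative, with a zero diagonal.
    property
        Edge-weight property: one of ``NFD`` (normalized fiber density),
        ``NF`` (number of fibers), ``MFL`` (median fiber length),
        ``MFA`` (median fractional anisotropy).
    scope
        ``"group"`` for a group-averaged SC, otherwise a subject identifier.
    """

    weights: np.ndarray
    property: str
    scope: str = "group"
    region_labels: list[str] | None = None

    def __post_init__(self) -> None:
        A = np.asarray(self.weights, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"SC weights must be square, got shape {A.shape}")
        if not np.all(np.isfinite(A)):
            raise ValueError("SC weights must be finite")
        asym = np.max(np.abs(A - A.T)) if A.size else 0.0
        if asym > _SYM_TOL * max(1.0, np.max(np.abs(A))):
            raise ValueError(f"SC weights asymmetric beyond tolerance ({asym:g})")
        A = (A + A.T) / 2.0
        if np.any(A < 0):
            raise ValueError("SC weights must be nonnegative")
        if np.any(np.diag(A) != 0):
            raise ValueError("SC diagonal must be zero")
        if self.property not in PROPERTIES:
            raise ValueError(f"unknown property {self.property!r}")
        self.weights = A

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class ShiftOperator:
    """One graph shift operator with its degree vector and total weight."""

    matrix: np.ndarray
    kind: str
    degree: np.ndarray
    total_weight: float


@dataclass
class GraphSpectrum:
    """Connectome harmonics: eigenvector basis and ascending eigenvalues.

    For symmetric operator kinds the basis is orthonormal.  For ``L_RW`` the
    eigenproblem is solved as the generalized symmetric problem
    ``L u = lam D u``, so columns of ``U`` are orthonormal under the
    degree-weighted inner product recorded in ``inner_product_weight``.
    """

    U: np.ndarray
    lam: np.ndarray
    kind: str
    orthonormal: bool
    inner_product_weight: np.ndarray | None = None

    @property
    def n_regions(self) -> int:
        return self.U.shape[0]


def build_group_sc(subject_scs: list[StructuralConnectome]) -> StructuralConnectome:
    """Element-wise mean of subject SCs sharing property and shape."""
    if not subject_scs:
        raise ValueError("need at least one SC")
    first = subject_scs[0]
    for sc in subject_scs[1:]:
        if sc.weights.shape != first.weights.shape:
            raise ValueError("SC shapes differ")
        if sc.property != first.property:
            raise ValueError("SC properties differ")
    mean_w = np.mean([sc.weights for sc in subject_scs], axis=0)
    return StructuralConnectome(mean_w, first.property, scope="group",
                                region_labels=first.region_labels)


def build_shift_operator(sc: StructuralConnectome, kind: str,
                         convention: str = "halved") -> ShiftOperator:
    """Build one of the four shift operators from a structural connectome.

    Parameters
    ----------
    sc
        Input connectome.
    kind
        One of ``L_U``, ``L_N``, ``L_RW``, ``L_Q``.
    convention
        For ``L_Q`` only: ``"halved"`` uses ``A - k k^T / (2M)`` with ``M = sum(k)``;
        ``"newman"`` uses ``A - k k^T / M`` (zero row sums).
    """
    if kind not in OPERATOR_KINDS:
        raise ValueError(f"unknown operator kind {kind!r}")
    A = sc.weights
    k = A.sum(axis=1)
    M = float(k.sum())
    if kind == "L_U":
        mat = np.diag(k) - A
    elif kind in ("L_N", "L_RW"):
        L = np.diag(k) - A
        with np.errstate(divide="ignore"):
            inv = np.where(k > 0, 1.0 / k, 0.0)  # Moore-Penrose inverse of D
        if kind == "L_N":
            s = np.sqrt(inv)
            mat = s[:, None] * L * s[None, :]
        else:
            mat = inv[:, None] * L
    else:  # L_Q
        if convention == "halved":
            denom = 2.0 * M
        elif convention == "newman":
            denom = M
        else:
            raise ValueError(f"unknown L_Q convention {convention!r}")
        if M == 0:
            raise ValueError("modularity matrix undefined for an empty graph")
        mat = A - np.outer(k, k) / denom
    return ShiftOperator(matrix=mat, kind=kind, degree=k, total_weight=M)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic sign: largest-magnitude entry of each column positive."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs[None, :]


def eigendecompose(op: ShiftOperator) -> GraphSpectrum:
    """Extract connectome harmonics with ascending eigenvalues.

    Symmetric kinds use a dense symmetric eigensolver and return an
    orthonormal basis.  ``L_RW`` is solved as ``L u = lam D u`` restricted to
    nonzero-degree regions (giving exactly the ``L_N`` eigenvalues); isolated
    regions contribute indicator eigenvectors with eigenvalue 0.
    """
    if not np.all(np.isfinite(op.matrix)):
        raise ValueError("operator has non-finite entries")
    R = op.matrix.shape[0]
    if op.kind in _SYMMETRIC_KINDS:
        sym = (op.matrix + op.matrix.T) / 2.0
        lam, U = scipy.linalg.eigh(sym)
        return GraphSpectrum(U=_fix_signs(U), lam=lam, kind=op.kind,
                             orthonormal=True)
    # L_RW: generalized symmetric problem on nonzero-degree nodes
    k = op.degree
    nz = k > 0
    L = _unnormalized_from_rw(op)  # L = D @ L_RW; isolated rows are zero
    lam_full = np.zeros(R)
    U_full = np.zeros((R, R))
    n_iso = int(np.sum(~nz))
    if np.any(nz):
        Lsub = L[np.ix_(nz, nz)]
        Dsub = np.diag(k[nz])
        lam_sub, U_sub = scipy.linalg.eigh((Lsub + Lsub.T) / 2.0, Dsub)
        lam_full[n_iso:] = lam_sub
        U_full[np.ix_(nz, np.arange(n_iso, R))] = U_sub
    # isolated nodes: indicator columns, eigenvalue 0, placed first so the
    # ascending order is preserved (lam_sub[0] == 0 for each component anyway)
    iso_idx = np.flatnonzero(~nz)
    for j, r in enumerate(iso_idx):
        U_full[r, j] = 1.0
    order = np.argsort(lam_full, kind="stable")
    lam_full = lam_full[order]
    U_full = U_full[:, order]
    return GraphSpectrum(U=_fix_signs(U_full), lam=lam_full, kind="L_RW",
                         orthonormal=False, inner_product_weight=k.copy())


def _unnormalized_from_rw(op: ShiftOperator) -> np.ndarray:
    """Recover ``L = D @ L_RW`` (rows of isolated nodes are zero)."""
    return op.degree[:, None] * op.matrix
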