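"""Natural cubic spline bases, log-spaced lag knots, and the cross-basis.

A distributed lag non-linear model represents the contribution of exposure
value ``x`` at lag ``l`` as a smooth bivariate surface

    f(x, l) = sum_{j,k} beta_{jk} B_j(x) C_k(l)

where ``B`` is a basis over exposure values and ``C`` a basis over lags.
The design row for an event-hour with lagged exposures ``q_0..q_L`` is the
*cross-basis*

    W[(j,k)] = sum_{l=0}^{L} B_j(q_l) C_k(l),

i.e. the tensor-product basis summed over the observed lag profile.  Columns
are ordered exposure-major: column ``(j, k)`` sits at index ``j * v_l + k``.

The exposure basis is a natural cubic spline (piecewise cubic, continuous
second derivatives, linear beyond the boundary knots), built from the cubic
B-spline basis by projecting out the two boundary second-derivative degrees
of freedom, exactly as the classical regression-spline construction does.
Evaluation beyond the boundary knots continues linearly with the boundary
value and slope, which is the defining property of the natural spline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "BasisSpec",
    "natural_cubic_basis",
    "evaluate_basis",
    "log_lag_knots",
    "CrossBasisMatrix",
    "cross_basis",
    "assemble_design",
    "DesignMatrix",
]


@dataclass(frozen=True)
class BasisSpec:
    """Specification of a one-dimensional basis.

    kind
        ``natural_cubic`` | ``linear`` | ``constant``.
    knots
        Internal knots (natural_cubic only), strictly inside the boundary.
    boundary
        Boundary knot pair; the spline is linear outside it.
    intercept
        Whether the basis spans the constant function.
    """

    kind: str
    knots: tuple = ()
    boundary: tuple = ()
    intercept: bool = False

    @property
    def df(self) -> int:
        if self.kind == "natural_cubic":
            return len(self.knots) + 1 + (1 if self.intercept else 0)
        if self.kind == "linear":
            return 1 + (1 if self.intercept else 0)
        if self.kind == "constant":
            return 1
        raise ValueError(f"unknown basis kind {self.kind!r}")

    def __post_init__(self):
        if self.kind not in ("natural_cubic", "linear", "constant"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "natural_cubic":
            if len(self.boundary) != 2 or not self.boundary[0] < self.boundary[1]:
                raise ValueError("boundary knots must be an increasing pair")
            k = np.asarray(self.knots, dtype=float)
            if k.size and (np.any(np.diff(k) <= 0)
                           or k[0] <= self.boundary[0] or k[-1] >= self.boundary[1]):
                raise ValueError("internal knots must be increasing and strictly "
                                 "inside the boundary knots")

    @classmethod
    def from_quantiles(cls, values: np.ndarray, df: int = 3,
                       intercept: bool = False) -> "BasisSpec":
        """Natural cubic spec with internal knots at equally spaced quantiles
        of ``values`` and boundary knots at its min/max."""
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        n_internal = df - 1 - (1 if intercept else 0)
        if n_internal < 0:
            raise ValueError("df too small for a natural cubic spline")
        probs = np.linspace(0, 1, n_internal + 2)[1:-1]
        knots = tuple(np.quantile(v, probs))
        return cls("natural_cubic", knots=knots,
                   boundary=(float(v.min()), float(v.max())), intercept=intercept)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "df": self.df, "knots": list(self.knots),
                "boundary": list(self.boundary), "intercept": self.intercept}

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        return cls(d["kind"], knots=tuple(d["knots"]),
                   boundary=tuple(d["boundary"]), intercept=d["intercept"])


def _ns_qr(spec: BasisSpec):
    """Full B-spline knot vector and the QR factor that imposes zero second
    derivative at both boundaries."""
    b0, b1 = spec.boundary
    t = np.concatenate([[b0] * 4, np.asarray(spec.knots, float), [b1] * 4])
    m = len(t) - 4
    # second derivative of every B-spline basis function at the boundaries
    const = np.empty((2, m))
    for i in range(m):
        c = np.zeros(m)
        c[i] = 1.0
        d2 = BSpline(t, c, 3).derivative(2)
        const[0, i] = d2(b0)
        const[1, i] = d2(b1)
    if not spec.intercept:
        const = const[:, 1:]
    q, _ = np.linalg.qr(const.T, mode="complete")
    return t, q[:, 2:]


def _ns_eval(x: np.ndarray, spec: BasisSpec, deriv: int = 0) -> np.ndarray:
    t, q = _ns_qr(spec)
    m = len(t) - 4
    design = BSpline.design_matrix(x, t, 3, extrapolate=False).toarray()
    if deriv:
        cols = []
        for i in range(m):
            c = np.zeros(m)
            c[i] = 1.0
            cols.append(BSpline(t, c, 3).derivative(deriv)(x))
        design = np.column_stack(cols)
    if not spec.intercept:
        design = design[:, 1:]
    return design @ q


def natural_cubic_basis(values: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Evaluate the natural cubic spline basis at ``values``.

    Returns an ``(n, df)`` matrix.  Values beyond the boundary knots are
    evaluated by linear extrapolation from the boundary value and slope.
    NaN inputs propagate to NaN rows.
    """
    if spec.kind != "natural_cubic":
        raise ValueError("spec is not a natural cubic basis")
    x = np.asarray(values, dtype=float).ravel()
    b0, b1 = spec.boundary
    out = np.full((x.size, spec.df), np.nan)
    finite = np.isfinite(x)
    xc = np.clip(x[finite], b0, b1)
    base = _ns_eval(xc, spec)
    # linear continuation beyond the boundary knots
    excess = x[finite] - np.clip(x[finite], b0, b1)
    outside = excess != 0
    if np.any(outside):
        slope = _ns_eval(xc[outside], spec, deriv=1)
        base[outside] += excess[outside, None] * slope
    out[finite] = base
    return out


def evaluate_basis(values: np.ndarray, spec: BasisSpec) -> np.ndarray:
    """Evaluate any :class:`BasisSpec` at ``values`` -> ``(n, df)`` matrix."""
    x = np.asarray(values, dtype=float).ravel()
    if spec.kind == "natural_cubic":
        return natural_cubic_basis(x, spec)
    if spec.kind == "constant":
        return np.ones((x.size, 1))
    if spec.kind == "linear":
        if spec.intercept:
            return np.column_stack([np.ones_like(x), x])
        return x[:, None]
    raise ValueError(f"unknown basis kind {spec.kind!r}")


def log_lag_knots(L: int, n_knots: int) -> np.ndarray:
    """Logarithmically spaced internal knots on the lag axis ``[0, L]``.

    Knot ``i`` (1-based) is ``exp(i * log(L) / (n_knots + 1))``, so knots are
    equally spaced on the log scale between lag 1 and lag L.  Log spacing puts
    more flexibility at short lags, where lag-response curves change fastest.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if n_knots < 1:
        raise ValueError("n_knots must be >= 1")
    if n_knots >= L:
        raise ValueError("n_knots must be < L")
    i = np.arange(1, n_knots + 1)
    return np.exp(i * np.log(L) / (n_knots + 1))


def lag_basis_spec(L: int, n_knots: int = 2) -> BasisSpec:
    """Default lag basis: natural cubic with intercept and log-spaced knots."""
    return BasisSpec("natural_cubic", knots=tuple(log_lag_knots(L, n_knots)),
                     boundary=(0.0, float(L)), intercept=True)


@dataclass
class CrossBasisMatrix:
    """Cross-basis design block plus the metadata needed to predict from it.

    ``W`` has one row per event-hour and ``v_x * v_l`` columns ordered
    exposure-major (column ``(j, k)`` at index ``j * v_l + k``).
    """

    W: np.ndarray
    exposure_spec: BasisSpec
    lag_spec: BasisSpec
    max_lag: int
    exposure_name: str

    @property
    def v_x(self) -> int:
        return self.exposure_spec.df

    @property
    def v_l(self) -> int:
        return self.lag_spec.df

    def contrast_vector(self, x: float, x_ref: float, lags: np.ndarray) -> np.ndarray:
        """Coefficient-space contrast for log OR(x vs x_ref) summed over
        ``lags``: c_{jk} = (B_j(x) - B_j(x_ref)) * sum_l C_k(l)."""
        bx = evaluate_basis(np.array([x]), self.exposure_spec)[0]
        br = evaluate_basis(np.array([x_ref]), self.exposure_spec)[0]
        C = evaluate_basis(np.asarray(lags, dtype=float), self.lag_spec)
        return np.outer(bx - br, C.sum(axis=0)).ravel()


def cross_basis(Q: np.ndarray, exposure_spec: BasisSpec, lag_spec: BasisSpec,
                exposure_name: str = "exposure") -> CrossBasisMatrix:
    """Build the cross-basis matrix from a lag matrix ``Q`` (n, L+1).

    ``Q[i, l]`` is the exposure at the row's event-hour minus ``l`` hours.
    ``Q`` must be fully observed: masked histories are resolved upstream.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2:
        raise ValueError("Q must be 2-dimensional (rows x lags)")
    if not np.all(np.isfinite(Q)):
        raise ValueError("cross_basis requires fully observed lag histories; "
                         "resolve masked cells upstream")
    n, n_lag = Q.shape
    L = n_lag - 1
    B = evaluate_basis(Q.ravel(), exposure_spec).reshape(n, n_lag, -1)
    C = evaluate_basis(np.arange(n_lag, dtype=float), lag_spec)
    W = np.einsum("nlj,lk->njk", B, C).reshape(n, -1)
    return CrossBasisMatrix(W, exposure_spec, lag_spec, L, exposure_name)


@dataclass
class DesignMatrix:
    """Stacked design: named column blocks aligned row-for-row."""

    X: np.ndarray
    column_names: list[str]
    blocks: dict = field(default_factory=dict)  # name -> slice

    def block(self, name: str) -> slice:
        return self.blocks[name]


def assemble_design(cross_bases: "list[CrossBasisMatrix]",
                    pollutants: "np.ndarray | None" = None,
                    pollutant_names: "list[str] | None" = None,
                    interaction_with: "np.ndarray | None" = None) -> DesignMatrix:
    """Stack cross-basis blocks, linear pollutant covariates, and optionally a
    temperature x humidity interaction block.

    The interaction block multiplies the *first* cross-basis block elementwise
    by ``interaction_with`` (the centred 24-h mean relative humidity of each
    event-hour), adding ``v_x * v_l`` columns: a rank-reduced interaction in
    which the modifier enters as a scalar.
    """
    if not cross_bases:
        raise ValueError("need at least one cross-basis block")
    n = cross_bases[0].W.shape[0]
    cols: list[np.ndarray] = []
    names: list[str] = []
    blocks: dict = {}
    for cb in cross_bases:
        if cb.W.shape[0] != n:
            raise ValueError(f"row mismatch in cross-basis block {cb.exposure_name!r}")
        blocks[cb.exposure_name] = slice(len(names), len(names) + cb.W.shape[1])
        names += [f"{cb.exposure_name}.b{j}.l{k}"
                  for j in range(cb.v_x) for k in range(cb.v_l)]
        cols.append(cb.W)
    if pollutants is not None and pollutants.size:
        pollutants = np.asarray(pollutants, dtype=float)
        if pollutants.shape[0] != n:
            raise ValueError("row mismatch in block 'pollutants'")
        if pollutant_names is None:
            pollutant_names = [f"pollutant{i}" for i in range(pollutants.shape[1])]
        blocks["pollutants"] = slice(len(names), len(names) + pollutants.shape[1])
        names += list(pollutant_names)
        cols.append(pollutants)
    if interaction_with is not None:
        z = np.asarray(interaction_with, dtype=float).ravel()
        if z.size != n:
            raise ValueError("row mismatch in block 'interaction'")
        cb0 = cross_bases[0]
        blocks["interaction"] = slice(len(names), len(names) + cb0.W.shape[1])
        names += [f"ix.{nm}" for nm in
                  (f"{cb0.exposure_name}.b{j}.l{k}"
                   for j in range(cb0.v_x) for k in range(cb0.v_l))]
        cols.append(cb0.W * z[:, None])
    return DesignMatrix(np.hstack(cols), names, blocks)
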