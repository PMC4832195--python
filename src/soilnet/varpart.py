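"""Hellinger transform, redundancy-analysis R² and three-factor variance
partitioning.

The response matrix (Hellinger-transformed, column-centred) is projected
onto every non-empty union of the three explanatory blocks; adjusted R²
(Ezekiel: 1 − (1 − R²)(n − 1)/(n − m − 1), with m the effective rank of
the predictor union) is decomposed by inclusion–exclusion into the three
unique fractions, three pairwise-shared fractions, the triple-shared
fraction, and the residual.  Shared fractions may legitimately be negative
under adjusted R².  Unique fractions are testable by permutation of the
residuals of the reduced model (the usual partial-RDA scheme).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import Metadata, SampleTable, ValidationError

FRACTION_KEYS = ("a", "b", "c", "ab", "ac", "bc", "abc", "residual")


def hellinger(table) -> np.ndarray:
    """Hellinger transform: y'_iv = sqrt(y_iv / Σ_v y_iv).

    Each transformed row has unit sum of squares.  Accepts a SampleTable
    or a plain non-negative array.
    """
    if isinstance(table, SampleTable):
        values = np.asarray(table.values, dtype=float)
        names = table.sample_ids
    else:
        values = np.asarray(table, dtype=float)
        names = tuple(range(values.shape[0]))
    if np.any(values < 0):
        raise ValidationError("Hellinger transform requires non-negative values")
    row_sums = values.sum(axis=1)
    if np.any(row_sums == 0):
        offender = names[int(np.where(row_sums == 0)[0][0])]
        raise ValidationError(f"all-zero row for sample {offender!r}")
    return np.sqrt(values / row_sums[:, None])


@dataclass(frozen=True)
class ExplanatoryBlock:
    """A named block of predictor columns (categoricals already expanded
    to indicators with one level dropped)."""

    name: str
    design_matrix: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.design_matrix, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if x.ndim != 2:
            raise ValidationError(f"block {self.name!r} design matrix must be 2-D")
        if not np.all(np.isfinite(x)):
            raise ValidationError(f"block {self.name!r} holds non-finite values")
        xc = x - x.mean(axis=0)
        if np.linalg.matrix_rank(xc) < x.shape[1]:
            raise ValidationError(
                f"block {self.name!r} has linearly dependent columns "
                f"(rank {np.linalg.matrix_rank(xc)} < {x.shape[1]})"
            )
        x = x.copy()
        x.setflags(write=False)
        object.__setattr__(self, "design_matrix", x)

    @property
    def n_columns(self) -> int:
        return self.design_matrix.shape[1]


def blocks_from_metadata(metadata: Metadata, sample_ids: Sequence[str] | None = None):
    """The study's three standard blocks: centred pH, site indicators
    (drop-first, alphabetical levels) and a single COF indicator."""
    frame = metadata.frame
    if sample_ids is not None:
        frame = frame.set_index("sample_id").loc[list(sample_ids)].reset_index()
    ph = frame["pH"].to_numpy(dtype=float)[:, None]
    ph = ph - ph.mean()
    site_levels = sorted(frame["site"].unique())
    site = np.column_stack([
        (frame["site"] == level).to_numpy(dtype=float) for level in site_levels[1:]
    ]) if len(site_levels) > 1 else np.zeros((len(frame), 0))
    fert = (frame["fertilization"] == "COF").to_numpy(dtype=float)[:, None]
    return (
        ExplanatoryBlock("pH", ph),
        ExplanatoryBlock("site", site),
        ExplanatoryBlock("fertilization", fert),
    )


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------


def _centre(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x - x.mean(axis=0)


def _orthonormal_basis(xc: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing SVD)."""
    if xc.shape[1] == 0:
        return np.zeros((xc.shape[0], 0))
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    cutoff = s.max(initial=0.0) * max(xc.shape) * np.finfo(float).eps
    return u[:, s > cutoff]


def _raw_r2(yc: np.ndarray, xc: np.ndarray):
    """Raw R² of the centred response on the centred predictor space,
    with the effective rank of the predictors."""
    q = _orthonormal_basis(xc)
    total = float(np.sum(yc ** 2))
    if total == 0.0:
        raise ValidationError("response matrix has zero total variance")
    fitted = float(np.sum((q.T @ yc) ** 2))
    return fitted / total, q.shape[1]


def _adjust(r2: float, n: int, m: int) -> float:
    if m >= n - 1:
        raise ValidationError(
            f"predictor rank {m} must be < n_samples − 1 = {n - 1} for adjusted R²"
        )
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def rda_adjusted_r2(response: np.ndarray, blocks: Sequence[ExplanatoryBlock]) -> float:
    """Adjusted R² of a (transformed) response on a union of blocks."""
    yc = _centre(response)
    xc = _centre(np.hstack([b.design_matrix for b in blocks]))
    r2, rank = _raw_r2(yc, xc)
    return _adjust(r2, yc.shape[0], rank)


@dataclass(frozen=True)
class VpaResult:
    """Eight variance fractions for three explanatory blocks.

    ``a``/``b``/``c`` are the unique fractions of the three blocks in the
    order given; ``ab``/``ac``/``bc`` pairwise-shared; ``abc``
    triple-shared; the eight fractions sum to 1 exactly.  Shared fractions
    can be negative under adjusted R².
    """

    block_names: tuple
    a: float
    b: float
    c: float
    ab: float
    ac: float
    bc: float
    abc: float
    residual: float
    adjusted: bool
    testable_fraction_pvalues: dict | None = None

    @property
    def total_explained(self) -> float:
        return 1.0 - self.residual

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in FRACTION_KEYS}

    def to_frame(self) -> pd.DataFrame:
        names = dict(zip("abc", self.block_names))
        labels = {
            "a": names["a"], "b": names["b"], "c": names["c"],
            "ab": f"{names['a']}∩{names['b']}",
            "ac": f"{names['a']}∩{names['c']}",
            "bc": f"{names['b']}∩{names['c']}",
            "abc": "∩".join(self.block_names),
            "residual": "residual",
        }
        rows = []
        pvals = self.testable_fraction_pvalues or {}
        for key in FRACTION_KEYS:
            rows.append({
                "fraction": key,
                "factors": labels[key],
                "value": getattr(self, key),
                "percent": 100.0 * getattr(self, key),
                "p_value": pvals.get(key, float("nan")),
            })
        return pd.DataFrame(rows)


def variance_partition(
    response: np.ndarray,
    block_a: ExplanatoryBlock,
    block_b: ExplanatoryBlock,
    block_c: ExplanatoryBlock,
    adjusted: bool = True,
) -> VpaResult:
    """Partition response variance among three blocks by inclusion–exclusion
    over the seven non-empty block unions."""
    yc = _centre(response)
    n = yc.shape[0]
    blocks = {"a": block_a, "b": block_b, "c": block_c}
    for blk in blocks.values():
        if blk.design_matrix.shape[0] != n:
            raise ValidationError(
                f"block {blk.name!r} has {blk.design_matrix.shape[0]} rows, response has {n}"
            )

    def union_r2(keys: str) -> float:
        xc = _centre(np.hstack([blocks[k].design_matrix for k in keys]))
        r2, rank = _raw_r2(yc, xc)
        return _adjust(r2, n, rank) if adjusted else r2

    r = {keys: union_r2(keys) for keys in ("a", "b", "c", "ab", "ac", "bc", "abc")}
    a = r["abc"] - r["bc"]
    b = r["abc"] - r["ac"]
    c = r["abc"] - r["ab"]
    ab = r["abc"] - r["c"] - a - b
    ac = r["abc"] - r["b"] - a - c
    bc = r["abc"] - r["a"] - b - c
    abc = r["abc"] - a - b - c - ab - ac - bc
    residual = 1.0 - r["abc"]
    return VpaResult(
        block_names=(block_a.name, block_b.name, block_c.name),
        a=a, b=b, c=c, ab=ab, ac=ac, bc=bc, abc=abc, residual=residual,
        adjusted=adjusted,
    )


def residual_percentage(total_explained_pct: float) -> float:
    """Unexplained percentage implied by a total-explained percentage
    (the closure identity residual = 100 − total explained)."""
    return 100.0 - total_explained_pct


# ---------------------------------------------------------------------------
# permutation test of unique fractions
# ---------------------------------------------------------------------------


def fraction_significance(
    response: np.ndarray,
    blocks: Sequence[ExplanatoryBlock],
    fraction_id: str,
    n_permutations: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value of a unique fraction (``"a"``, ``"b"`` or ``"c"``).

    Tests the target block given the other two by freely permuting the
    residuals of the reduced model; the statistic is the partial pseudo-F
    on raw R².  p = (1 + #{F* ≥ F}) / (1 + n_permutations).
    """
    if fraction_id not in ("a", "b", "c"):
        raise ValidationError(
            f"only unique fractions 'a', 'b', 'c' are individually testable, "
            f"got {fraction_id!r}"
        )
    if len(blocks) != 3:
        raise ValidationError("exactly three blocks are required")
    idx = "abc".index(fraction_id)
    target = blocks[idx]
    reduced = [blk for i, blk in enumerate(blocks) if i != idx]

    yc = _centre(response)
    n = yc.shape[0]
    q_red = _orthonormal_basis(_centre(np.hstack([b.design_matrix for b in reduced])))
    q_full = _orthonormal_basis(
        _centre(np.hstack([b.design_matrix for b in (reduced + [target])]))
    )
    m_red, m_full = q_red.shape[1], q_full.shape[1]
    m_target = m_full - m_red
    if m_target == 0:
        raise ValidationError(
            f"block {target.name!r} adds no independent columns beyond the others"
        )
    if m_full >= n - 1:
        raise ValidationError("full model leaves no residual degrees of freedom")

    def pseudo_f(y: np.ndarray) -> float:
        total = float(np.sum(y ** 2))
        fit_red = float(np.sum((q_red.T @ y) ** 2))
        fit_full = float(np.sum((q_full.T @ y) ** 2))
        num = (fit_full - fit_red) / m_target
        den = (total - fit_full) / (n - m_full - 1)
        return num / den if den > 0 else float("inf")

    observed = pseudo_f(yc)
    fitted_red = q_red @ (q_red.T @ yc)
    residuals = yc - fitted_red

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    perms = np.stack([rng.permutation(n) for _ in range(n_permutations)])
    y_star = fitted_red[None, :, :] + residuals[perms]       # (B, n, p)
    tot = np.einsum("bij,bij->b", y_star, y_star)
    proj_red = np.einsum("ni,bnp->bip", q_red, y_star) if m_red else None
    fit_red_ss = (
        np.einsum("bip,bip->b", proj_red, proj_red) if m_red else np.zeros(n_permutations)
    )
    proj_full = np.einsum("ni,bnp->bip", q_full, y_star)
    fit_full_ss = np.einsum("bip,bip->b", proj_full, proj_full)
    num = (fit_full_ss - fit_red_ss) / m_target
    den = (tot - fit_full_ss) / (n - m_full - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_star = np.where(den > 0, num / den, np.inf)
    exceed = int(np.sum(f_star >= observed - 1e-12))
    return (1 + exceed) / (1 + n_permutations)


def vpa_with_significance(
    response: np.ndarray,
    block_a: ExplanatoryBlock,
    block_b: ExplanatoryBlock,
    block_c: ExplanatoryBlock,
    adjusted: bool = True,
    n_permutations: int = 999,
    seed: int = 0,
) -> VpaResult:
    """Variance partition plus permutation p-values for the unique fractions."""
    result = variance_partition(response, block_a, block_b, block_c, adjusted=adjusted)
    blocks = [block_a, block_b, block_c]
    pvals = {
        key: fraction_significance(response, blocks, key, n_permutations, seed)
        for key in ("a", "b", "c")
    }
    return VpaResult(
        block_names=result.block_names,
        a=result.a, b=result.b, c=result.c,
        ab=result.ab, ac=result.ac, bc=result.bc, abc=result.abc,
        residual=result.residual, adjusted=result.adjusted,
        testable_fraction_pvalues=pvals,
    )
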