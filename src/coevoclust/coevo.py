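"""Coevolution statistics: combined distances, the ICQ, and noise thresholds.

The *internal coevolutionary quotient* (ICQ) summarises how many gene pairs
in a cluster fall below empirically set distance thresholds:

    ICQ = 1 - g / (2 * d * (d - 1))

where ``d`` is the number of genes and ``g`` counts qualifying off-diagonal
matrix entries — strict distances strictly below ``strict_cutoff`` (default
0.7) plus combined distances at or below ``combined_factor`` (default 0.6)
times the combined-matrix maximum.  Lower ICQ means more internal
coevolution; an ICQ above the noise threshold (default 0.708, derived from
control gene-cluster sets) indicates that no statistically relevant internal
coevolution can be established.

The noise threshold itself is estimated as the crossing point of two
Gaussian kernel density estimates — one ICQ sample from coevolving sets, one
from randomly assembled sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import brentq
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdConfig",
    "ICQResult",
    "combine_matrices",
    "count_coevolved_entries",
    "icq",
    "kde_intersection",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Distance thresholds entering the ICQ.

    ``strict_cutoff`` is compared with "<", ``combined_factor`` scales the
    combined-matrix maximum and is compared with "<=".  The noise threshold
    is advisory metadata: the verdict is reported, never used to halt an
    analysis.
    """

    strict_cutoff: float = 0.7
    combined_factor: float = 0.6
    icq_noise_threshold: float = 0.708

    def __post_init__(self) -> None:
        if not (0.0 < self.strict_cutoff <= 1.0):
            raise ValueError("strict_cutoff must be in (0, 1]")
        if not (0.0 < self.combined_factor <= 1.0):
            raise ValueError("combined_factor must be in (0, 1]")
        if not (0.0 < self.icq_noise_threshold < 1.0):
            raise ValueError("icq_noise_threshold must be in (0, 1)")


@dataclass
class ICQResult:
    """ICQ value with its qualifying-entry ledger.

    ``qualifying_pairs`` lists each unordered gene pair once per matrix in
    which it qualifies; under the (default) ordered-entry convention each
    such pair contributes 2 to ``g``.
    """

    d: int
    g: int
    icq: float
    qualifying_pairs: list[tuple[str, str, str]]
    above_noise: bool
    convention: str = "ordered"
    noise_threshold: float = 0.708
    combination: str = "sum"

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["qualifying_pairs"] = [list(t) for t in self.qualifying_pairs]
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _check_square_symmetric(m: np.ndarray, name: str) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got {m.shape}")
    if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T), atol=1e-12):
        raise ValueError(f"{name} must be symmetric")
    return m


def combine_matrices(
    strict: np.ndarray, evolutionary: np.ndarray, method: str = "sum"
) -> np.ndarray:
    """Element-wise combination of the strict and evolutionary matrices.

    Default is the sum; ``method="mean"`` halves it.  Because the combined
    threshold is taken relative to the matrix maximum, any positive scaling
    is immaterial to the ICQ; the choice is recorded in output metadata.
    NaN in either parent propagates to the combined matrix.
    """
    s = _check_square_symmetric(strict, "strict")
    e = _check_square_symmetric(evolutionary, "evolutionary")
    if s.shape != e.shape:
        raise ValueError(f"shape mismatch: strict {s.shape} vs evolutionary {e.shape}")
    if method == "sum":
        combined = s + e
    elif method == "mean":
        combined = (s + e) / 2.0
    else:
        raise ValueError(f"unknown combination method {method!r}")
    np.fill_diagonal(combined, 0.0)
    return combined


def _qualifying_pairs(
    strict: np.ndarray, combined: np.ndarray, cfg: ThresholdConfig,
    gene_ids: list[str] | None,
) -> list[tuple[str, str, str]]:
    d = strict.shape[0]
    names = gene_ids if gene_ids is not None else [str(i) for i in range(d)]
    pairs: list[tuple[str, str, str]] = []
    finite_combined = combined[np.isfinite(combined)]
    cmax = finite_combined.max() if finite_combined.size else np.nan
    for i in range(d):
        for j in range(i + 1, d):
            sv = strict[i, j]
            if np.isfinite(sv) and sv < cfg.strict_cutoff:
                pairs.append((names[i], names[j], "strict"))
            cv = combined[i, j]
            if np.isfinite(cv) and np.isfinite(cmax) and cv <= cfg.combined_factor * cmax:
                pairs.append((names[i], names[j], "combined"))
    return pairs


def count_coevolved_entries(
    strict: np.ndarray,
    combined: np.ndarray,
    cfg: ThresholdConfig | None = None,
    convention: str = "ordered",
) -> int:
    """Count qualifying sub-threshold entries across both matrices.

    Under the default *ordered* convention every qualifying unordered pair
    contributes 2 per matrix (both (i,j) and (j,i) entries count), so g
    ranges over [0, 2*d*(d-1)].  NaN entries never qualify; an all-NaN
    combined matrix contributes 0 with a warning.
    """
    cfg = cfg or ThresholdConfig()
    s = _check_square_symmetric(strict, "strict")
    c = _check_square_symmetric(combined, "combined")
    if s.shape != c.shape:
        raise ValueError("strict and combined matrices must share a shape")
    if not np.isfinite(c[~np.eye(c.shape[0], dtype=bool)]).any():
        logger.warning("combined matrix is all-NA; combined term contributes 0")
    pairs = _qualifying_pairs(s, c, cfg, None)
    if convention == "ordered":
        return 2 * len(pairs)
    if convention == "unordered":
        return len(pairs)
    raise ValueError(f"unknown counting convention {convention!r}")


def icq(
    strict: np.ndarray,
    combined: np.ndarray,
    cfg: ThresholdConfig | None = None,
    gene_ids: list[str] | None = None,
    convention: str = "ordered",
    combination: str = "sum",
) -> ICQResult:
    """Compute the ICQ for one distance-matrix set.

    ``icq = 1 - g / (2*d*(d-1))``; with the ordered-entry convention the
    value spans [0, 1]: 1 when nothing qualifies, 0 at saturation.
    ``above_noise`` flags ICQ values above the noise threshold, meaning no
    statistically relevant internal coevolution could be determined.
    """
    cfg = cfg or ThresholdConfig()
    s = _check_square_symmetric(strict, "strict")
    d = s.shape[0]
    if d < 2:
        raise ValueError("ICQ needs at least 2 genes")
    c = _check_square_symmetric(combined, "combined")
    pairs = _qualifying_pairs(s, c, cfg, gene_ids)
    g = 2 * len(pairs) if convention == "ordered" else len(pairs)
    denom = 2 * d * (d - 1) if convention == "ordered" else d * (d - 1)
    value = 1.0 - g / denom
    return ICQResult(
        d=d,
        g=g,
        icq=value,
        qualifying_pairs=pairs,
        above_noise=value > cfg.icq_noise_threshold,
        convention=convention,
        noise_threshold=cfg.icq_noise_threshold,
        combination=combination,
    )


def kde_intersection(
    sample_a, sample_b, grid_size: int = 2048
) -> float:
    """Crossing point of two Gaussian KDEs between their modes.

    Both samples must hold >= 10 values in [0, 1].  Each sample gets a
    Gaussian KDE with Silverman bandwidth; the crossing is the abscissa
    between the two density modes where ``density_a - density_b`` changes
    sign, refined by root bracketing.  Deterministic given the inputs.
    Returns NaN (with a logged diagnostic) when no sign change exists, e.g.
    for identical samples.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    for name, x in (("sample_a", a), ("sample_b", b)):
        if x.size < 10:
            raise ValueError(f"{name} needs >= 10 values, got {x.size}")
        if np.nanmin(x) < 0 or np.nanmax(x) > 1:
            raise ValueError(f"{name} values must lie in [0, 1]")

    kde_a = gaussian_kde(a, bw_method="silverman")
    kde_b = gaussian_kde(b, bw_method="silverman")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    pad = 0.05 * (hi - lo if hi > lo else 1.0)
    grid = np.linspace(lo - pad, hi + pad, grid_size)
    da = kde_a(grid)
    db = kde_b(grid)

    mode_a = grid[int(np.argmax(da))]
    mode_b = grid[int(np.argmax(db))]
    left, right = sorted((mode_a, mode_b))
    mask = (grid >= left) & (grid <= right)
    sub = grid[mask]
    diff = da[mask] - db[mask]
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if sub.size < 2 or sign_change.size == 0:
        logger.warning(
            "no KDE crossing between modes %.4f and %.4f; returning NA",
            left, right,
        )
        return float("nan")
    i = int(sign_change[0])
    f = lambda x: kde_a(x)[0] - kde_b(x)[0]
    try:
        return float(brentq(f, sub[i], sub[i + 1]))
    except ValueError:
        # densities touch without crossing inside the bracket
        return float((sub[i] + sub[i + 1]) / 2.0)
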