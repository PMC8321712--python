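"""GrabCut foreground extraction by iterated GMM fitting and graph min-cut.

Segmentation is posed as a binary labeling a (0 background, 1 foreground)
minimizing the Gibbs energy

    E(a, k, theta, z) = U(a, k, theta, z) + V(a, z),

where the data term U sums, over pixels, the negative log-likelihood of the
pixel color z_n under its class's Gaussian mixture (K = 5 components per
class, each pixel scored by its best component), and the smoothness term

    V = gamma * sum over neighbor pairs (m, n) with a_m != a_n
        of exp(-beta * ||z_m - z_n||^2)

penalizes label changes across low-contrast edges.  beta defaults to
1 / (2 <||z_m - z_n||^2>) averaged over neighbor pairs, which adapts the
boundary term to the image contrast.  The user supplies a rectangle: pixels
outside it are hard background; pixels inside are possible foreground.  Each
iteration (i) assigns every pixel its best mixture component, (ii) refits
the per-component parameters, and (iii) solves an exact s-t min-cut for the
optimal labeling, so the energy trace is non-increasing; iteration stops
when the relative energy change falls below a tolerance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from networkx.algorithms.flow import boykov_kolmogorov
from scipy import ndimage
from skimage.morphology import closing, disk, opening
from sklearn.cluster import KMeans

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class GrabCutConfig:
    gamma: float = 50.0
    n_components: int = 5
    connectivity: int = 8  # neighborhood system: 4 or 8
    max_iters: int = 10
    tol: float = 1e-3  # relative energy change at convergence
    cov_reg: float = 1e-6  # added to covariance diagonals
    beta: float | None = None  # None: 1/(2<||dz||^2>) from the image

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.beta is not None and self.beta <= 0:
            raise ValueError("beta must be positive when given")


@dataclass(frozen=True)
class Trimap:
    """Initial labels (0 bg / 1 possible fg) and the hard-constraint mask."""

    labels: np.ndarray
    hard: np.ndarray  # True where the label may never change


@dataclass(frozen=True)
class ClassGmm:
    """One class's mixture: weights (K,), means (K, 3), covariances (K, 3, 3)."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def component_nll(self, pixels: np.ndarray) -> np.ndarray:
        """-log(pi_k * N(z; mu_k, Sigma_k)) for every pixel x component."""
        out = np.empty((len(pixels), len(self.weights)))
        for k, (w, mu, cov) in enumerate(
            zip(self.weights, self.means, self.covariances)
        ):
            if w <= 0:
                out[:, k] = np.inf
                continue
            chol = np.linalg.cholesky(cov)
            sol = np.linalg.solve(chol, (pixels - mu).T)
            maha = np.einsum("ij,ij->j", sol, sol)
            logdet = 2.0 * np.log(np.diag(chol)).sum()
            out[:, k] = -np.log(w) + 0.5 * (maha + logdet + 3 * _LOG_2PI)
        return out

    def nll(self, pixels: np.ndarray) -> np.ndarray:
        """Per-pixel data cost under the best component."""
        return self.component_nll(pixels).min(axis=1)


@dataclass(frozen=True)
class GmmModel:
    foreground: ClassGmm
    background: ClassGmm


@dataclass(frozen=True)
class EnergyBreakdown:
    total: float
    data: float
    smoothness: float
    iteration: int = 0


def init_trimap(image: np.ndarray, rect: tuple) -> Trimap:
    """Initialize labels from a rectangle (r0, c0, r1, c1), end-exclusive.

    Pixels inside the rectangle are possible foreground (1); pixels outside
    are hard background (0) and stay background in every later iteration.
    """
    h, w = np.asarray(image).shape[:2]
    r0, c0, r1, c1 = rect
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"rectangle {rect} empty or outside a {h}x{w} image")
    labels = np.zeros((h, w), dtype=np.uint8)
    labels[r0:r1, c0:c1] = 1
    hard = labels == 0
    return Trimap(labels=labels, hard=hard)


def _fit_class(
    pixels: np.ndarray, n_components: int, cov_reg: float, seed: int
) -> ClassGmm:
    if len(pixels) < n_components:
        warnings.warn(
            f"only {len(pixels)} pixels in class; "
            f"reducing mixture to {len(pixels)} components",
            stacklevel=3,
        )
    n_distinct = len(np.unique(pixels, axis=0))
    k = max(1, min(n_components, len(pixels), n_distinct))
    if k == 1:
        assign = np.zeros(len(pixels), dtype=int)
    else:
        assign = KMeans(n_clusters=k, n_init=3, random_state=seed).fit_predict(
            pixels
        )
    return _refit(pixels, assign, k, cov_reg)


def _refit(
    pixels: np.ndarray, assign: np.ndarray, k: int, cov_reg: float
) -> ClassGmm:
    weights = np.zeros(k)
    means = np.zeros((k, 3))
    covs = np.tile(np.eye(3) * cov_reg, (k, 1, 1))
    for comp in range(k):
        sel = pixels[assign == comp]
        if len(sel) == 0:
            continue
        weights[comp] = len(sel) / len(pixels)
        means[comp] = sel.mean(axis=0)
        centered = sel - means[comp]
        covs[comp] = centered.T @ centered / len(sel) + np.eye(3) * cov_reg
    return ClassGmm(weights=weights, means=means, covariances=covs)


def fit_gmms(
    image: np.ndarray,
    labels: np.ndarray,
    *,
    n_components: int = 5,
    cov_reg: float = 1e-6,
    seed: int = 0,
) -> GmmModel:
    """Fit per-class color GMMs (k-means init, then moment refit).

    Both classes must be nonempty; a class with fewer pixels than components
    gets a reduced mixture with a warning.
    """
    pixels = np.asarray(image, dtype=float).reshape(-1, 3)
    flat = np.asarray(labels).ravel().astype(bool)
    if not flat.any() or flat.all():
        raise ValueError("both foreground and background must be nonempty")
    return GmmModel(
        foreground=_fit_class(pixels[flat], n_components, cov_reg, seed),
        background=_fit_class(pixels[~flat], n_components, cov_reg, seed),
    )


def _neighbor_pairs(shape: tuple, connectivity: int):
    """Index pairs (flat) and the offset list of the neighborhood system."""
    h, w = shape
    idx = np.arange(h * w).reshape(h, w)
    offsets = [(0, 1), (1, 0)]
    if connectivity == 8:
        offsets += [(1, 1), (1, -1)]
    pairs_m, pairs_n = [], []
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), h - max(0, dr)
        c0, c1 = max(0, -dc), w - max(0, dc)
        if r1 <= r0 or c1 <= c0:
            continue
        pairs_m.append(idx[r0:r1, c0:c1].ravel())
        pairs_n.append(idx[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel())
    return np.concatenate(pairs_m), np.concatenate(pairs_n)


def auto_beta(image: np.ndarray, connectivity: int = 8) -> float:
    """Contrast-adaptive beta = 1 / (2 <||z_m - z_n||^2>) over neighbors."""
    pixels = np.asarray(image, dtype=float).reshape(-1, 3)
    m, n = _neighbor_pairs(np.asarray(image).shape[:2], connectivity)
    mean_sq = float(np.sum((pixels[m] - pixels[n]) ** 2, axis=1).mean())
    return 0.0 if mean_sq == 0 else 1.0 / (2.0 * mean_sq)


def gibbs_energy(
    image: np.ndarray,
    labels: np.ndarray,
    gmm: GmmModel,
    cfg: GrabCutConfig | None = None,
    *,
    iteration: int = 0,
) -> EnergyBreakdown:
    """Evaluate E = U + V for a labeling under a fitted mixture model."""
    cfg = cfg or GrabCutConfig()
    pixels = np.asarray(image, dtype=float).reshape(-1, 3)
    flat = np.asarray(labels).ravel().astype(bool)
    data = float(
        gmm.foreground.nll(pixels[flat]).sum()
        + gmm.background.nll(pixels[~flat]).sum()
    )
    beta = cfg.beta if cfg.beta is not None else auto_beta(image, cfg.connectivity)
    m, n = _neighbor_pairs(np.asarray(image).shape[:2], cfg.connectivity)
    cut = flat[m] != flat[n]
    weights = np.exp(-beta * np.sum((pixels[m] - pixels[n]) ** 2, axis=1))
    smooth = float(cfg.gamma * weights[cut].sum())
    return EnergyBreakdown(
        total=data + smooth, data=data, smoothness=smooth, iteration=iteration
    )


def _min_cut_labels(
    pixels: np.ndarray,
    shape: tuple,
    gmm: GmmModel,
    hard_bg: np.ndarray,
    beta: float,
    cfg: GrabCutConfig,
) -> np.ndarray:
    """Exact optimal labeling for fixed GMMs via Boykov-Kolmogorov max-flow."""
    n_pix = len(pixels)
    d_fg = gmm.foreground.nll(pixels)
    d_bg = gmm.background.nll(pixels)
    m, n = _neighbor_pairs(shape, cfg.connectivity)
    w_pair = cfg.gamma * np.exp(
        -beta * np.sum((pixels[m] - pixels[n]) ** 2, axis=1)
    )
    huge = float(d_fg[~hard_bg].sum() + d_bg.sum() + w_pair.sum() + 1.0)

    g = nx.Graph()
    # t-links: cutting the sink edge pays the foreground cost, the source
    # edge the background cost; hard background gets an uncuttable sink link
    src_cap = np.where(hard_bg, 0.0, d_bg)
    sink_cap = np.where(hard_bg, huge, d_fg)
    g.add_weighted_edges_from(
        zip(np.full(n_pix, -1), range(n_pix), src_cap), weight="capacity"
    )
    g.add_weighted_edges_from(
        zip(range(n_pix), np.full(n_pix, -2), sink_cap), weight="capacity"
    )
    g.add_weighted_edges_from(zip(m, n, w_pair), weight="capacity")
    _, (source_side, _) = nx.minimum_cut(
        g, -1, -2, capacity="capacity", flow_func=boykov_kolmogorov
    )
    labels = np.zeros(n_pix, dtype=np.uint8)
    labels[list(source_side - {-1})] = 1
    return labels.reshape(shape)


def grabcut(
    image: np.ndarray,
    rect: tuple,
    cfg: GrabCutConfig | None = None,
    *,
    seed: int = 0,
) -> tuple[np.ndarray, list[EnergyBreakdown]]:
    """Iterative GrabCut segmentation inside a user rectangle.

    Returns the final boolean foreground mask and the per-iteration energy
    trace (non-increasing; iteration stops on convergence, the iteration cap,
    or when a step would not lower the energy).
    """
    cfg = cfg or GrabCutConfig()
    img = np.asarray(image, dtype=float)
    trimap = init_trimap(img, rect)
    labels = trimap.labels.copy()
    pixels = img.reshape(-1, 3)
    hard_bg = trimap.hard.ravel()
    beta = cfg.beta if cfg.beta is not None else auto_beta(img, cfg.connectivity)

    trace: list[EnergyBreakdown] = []
    gmm = fit_gmms(
        img, labels, n_components=cfg.n_components, cov_reg=cfg.cov_reg,
        seed=seed,
    )
    for iteration in range(cfg.max_iters):
        if iteration > 0:
            gmm = _reassign_and_refit(pixels, labels, gmm, cfg)
        new_labels = _min_cut_labels(
            pixels, labels.shape, gmm, hard_bg, beta, cfg
        )
        if not new_labels.any():  # cut emptied the foreground; keep previous
            new_labels = labels
        energy = gibbs_energy(img, new_labels, gmm, cfg, iteration=iteration)
        if trace and energy.total > trace[-1].total:
            break  # no further improvement possible; keep the previous state
        labels = new_labels
        trace.append(energy)
        if (
            len(trace) > 1
            and abs(trace[-2].total - trace[-1].total)
            <= cfg.tol * abs(trace[-2].total)
        ):
            break
    return labels.astype(bool), trace


def _reassign_and_refit(
    pixels: np.ndarray, labels: np.ndarray, gmm: GmmModel, cfg: GrabCutConfig
) -> GmmModel:
    flat = labels.ravel().astype(bool)
    out = {}
    for name, cls, sel in (
        ("foreground", gmm.foreground, flat),
        ("background", gmm.background, ~flat),
    ):
        pix = pixels[sel]
        assign = cls.component_nll(pix).argmin(axis=1)
        out[name] = _refit(pix, assign, len(cls.weights), cfg.cov_reg)
    return GmmModel(**out)


def smooth_boundary(
    mask: np.ndarray, *, radius: int = 2, max_area_change: float = 0.05
) -> np.ndarray:
    """Morphologically smooth a foreground contour.

    Opening removes boundary salt, closing fills boundary pepper.  If the
    smoothing at ``radius`` changes the foreground area by more than
    ``max_area_change`` (fraction), the radius is reduced; if even radius 1
    exceeds the bound the mask is returned unchanged.
    """
    mask = np.asarray(mask).astype(bool)
    area = mask.sum()
    if area == 0:
        raise ValueError("cannot smooth an empty mask")
    for r in range(radius, 0, -1):
        footprint = disk(r)
        smoothed = closing(opening(mask, footprint), footprint)
        if abs(int(smoothed.sum()) - int(area)) <= max_area_change * area:
            return smoothed
    return mask.copy()


def segmentation_accuracy(mask: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pixels on which two masks agree."""
    mask, truth = np.asarray(mask, bool), np.asarray(truth, bool)
    return float((mask == truth).mean())
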