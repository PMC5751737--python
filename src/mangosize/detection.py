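"""HOG-feature cascade detection of fruit in night canopy images.

A mango under LED illumination presents a bright, smooth arc edge that is
cheap to characterise with Histograms of Oriented Gradients: per-cell
orientation histograms (6x6 px cells, 9 unsigned bins) normalised over 2x2
cell blocks.  Detection slides a fixed window over an image pyramid and runs
each window through a staged cascade of boosted decision stumps; most
windows are rejected in the first stage, which keeps the detector fast
enough for in-field use.  Raw window hits are grouped by overlap and a group
must contain at least ``merge_threshold`` raw hits to be reported — a strict
merge threshold (default 8) trades recall for the near-zero false-positive
rate that sizing requires.

The detector contract is pluggable: any callable mapping a raster to a list
of :class:`BoundingBox` can replace :func:`detect_fruit` downstream.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize as _sk_resize
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "BoundingBox",
    "DetectorConfig",
    "DetectorModel",
    "mirror_horizontal",
    "hog_cell_histograms",
    "hog_features",
    "train_detector",
    "detect_fruit",
    "save_model",
    "load_model",
]

MODEL_FORMAT = "mangosize-hog-cascade-v1"


@dataclass(frozen=True)
class BoundingBox:
    """Half-open pixel box [x0, x1) x [y0, y1), 0-based, origin top-left."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError("box must have positive width and height")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x0 + self.x1) / 2.0, (self.y0 + self.y1) / 2.0)

    def clip(self, width: int, height: int) -> "BoundingBox":
        return BoundingBox(
            max(0, self.x0), max(0, self.y0), min(width, self.x1), min(height, self.y1)
        )

    def iou(self, other: "BoundingBox") -> float:
        ix0, iy0 = max(self.x0, other.x0), max(self.y0, other.y0)
        ix1, iy1 = min(self.x1, other.x1), min(self.y1, other.y1)
        if ix1 <= ix0 or iy1 <= iy0:
            return 0.0
        inter = (ix1 - ix0) * (iy1 - iy0)
        return inter / float(self.area + other.area - inter)


@dataclass(frozen=True)
class DetectorConfig:
    """Layout and training hyper-parameters of the HOG cascade.

    The 6-px cell is the load-bearing choice (a fruit edge at 2 m spans a
    handful of cells); blocks are 2x2 cells with L2 normalisation and 9
    unsigned orientation bins.  The pyramid covers windows of ~40-160 px at
    a 1.2 scale step, spanning fruit of 50-160 px extent at 1-3 m working
    distance.
    """

    window: int = 48
    cell: int = 6
    n_bins: int = 9
    block: int = 2
    n_stages: int = 10
    stage_fpr: float = 0.5
    stage_tpr: float = 0.995
    n_estimators: int = 60
    scale_step: float = 1.12
    min_window: int = 40
    max_window: int = 160
    #: pixel stride of the sliding window, realised as offset cell grids;
    #: must divide the cell size
    stride: int = 3
    merge_threshold: int = 8
    merge_iou: float = 0.4
    #: fraction of the window the fruit's long axis occupies in training
    #: snips; reported boxes are shrunk by this factor to bound the fruit
    box_shrink: float = 0.875

    def __post_init__(self) -> None:
        if self.merge_threshold < 1:
            raise ValueError("merge_threshold must be >= 1")
        if self.window % self.cell:
            raise ValueError("window must be a multiple of the cell size")


@dataclass
class DetectorModel:
    """A trained cascade: per-stage boosted stumps and pass thresholds."""

    config: DetectorConfig
    stages: list = field(default_factory=list)  # [(AdaBoostClassifier, float)]
    seed: int = 0
    format: str = MODEL_FORMAT

    @property
    def merge_threshold(self) -> int:
        return self.config.merge_threshold

    def compiled_stages(self) -> list:
        """Stage stumps as numpy arrays (cached) for fast grid scoring."""
        if not hasattr(self, "_compiled"):
            self._compiled = [
                (_compile_stage(clf), thr) for clf, thr in self.stages
            ]
        return self._compiled


def mirror_horizontal(raster: np.ndarray) -> np.ndarray:
    """Reverse column order (the RGB-D unit streams a mirrored image)."""
    raster = np.asarray(raster)
    if raster.size == 0:
        raise ValueError("empty raster")
    return raster[:, ::-1].copy()


def _to_gray(raster: np.ndarray) -> np.ndarray:
    raster = np.asarray(raster, dtype=float)
    if raster.ndim == 3:
        r, g, b = raster[..., 0], raster[..., 1], raster[..., 2]
        return 0.299 * r + 0.587 * g + 0.114 * b
    return raster


def hog_cell_histograms(gray: np.ndarray, cell: int = 6, n_bins: int = 9) -> np.ndarray:
    """Per-cell unsigned orientation histograms with hard bin assignment.

    Gradients are central differences (one-sided at the borders); each pixel
    votes its gradient magnitude into one of ``n_bins`` bins over [0, 180).
    Returns an array of shape (rows // cell, cols // cell, n_bins).
    """
    gray = np.asarray(gray, dtype=float)
    rows, cols = gray.shape
    ncy, ncx = rows // cell, cols // cell
    gray = gray[: ncy * cell, : ncx * cell]
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    ang = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    bins = np.minimum((ang / (180.0 / n_bins)).astype(int), n_bins - 1)
    hist = np.zeros((ncy, ncx, n_bins), dtype=float)
    cy = np.arange(ncy * cell) // cell
    cx = np.arange(ncx * cell) // cell
    flat_idx = (
        cy[:, None] * (ncx * n_bins) + cx[None, :] * n_bins + bins
    )
    np.add.at(hist.reshape(-1), flat_idx.ravel(), mag.ravel())
    return hist


def _block_normalize(cells: np.ndarray, block: int = 2, eps: float = 1e-6) -> np.ndarray:
    """L2-normalised overlapping blocks of ``block x block`` cells.

    Shape (ncy, ncx, n_bins) -> (ncy-block+1, ncx-block+1, block*block*n_bins).
    An all-zero block stays all-zero (degenerate snips yield zero vectors).
    """
    ncy, ncx, n_bins = cells.shape
    view = sliding_window_view(cells, (block, block), axis=(0, 1))
    # view shape: (nby, nbx, n_bins, block, block) -> flatten feature axis
    nby, nbx = view.shape[0], view.shape[1]
    flat = view.transpose(0, 1, 3, 4, 2).reshape(nby, nbx, block * block * n_bins)
    norms = np.sqrt(np.sum(flat * flat, axis=-1, keepdims=True))
    return flat / np.maximum(norms, eps)


def hog_features(
    gray_snip: np.ndarray, cell: int = 6, n_bins: int = 9, block: int = 2
) -> np.ndarray:
    """HOG descriptor of one snip (flattened block-normalised histograms).

    Snips whose dimensions are not cell multiples are reflect-padded up to
    the next multiple.  A constant snip yields the all-zero vector.
    """
    gray = _to_gray(gray_snip)
    rows, cols = gray.shape
    pr = (-rows) % cell
    pc = (-cols) % cell
    if pr or pc:
        gray = np.pad(gray, ((0, pr), (0, pc)), mode="reflect")
    cells = hog_cell_histograms(gray, cell=cell, n_bins=n_bins)
    blocks = _block_normalize(cells, block=block)
    return blocks.ravel()


def _snip_matrix(snips, config: DetectorConfig) -> np.ndarray:
    """Resize snips to the model window and stack their HOG descriptors."""
    feats = []
    w = config.window
    for s in snips:
        g = _to_gray(s)
        if g.shape != (w, w):
            g = _sk_resize(g, (w, w), anti_aliasing=True, preserve_range=True)
        feats.append(
            hog_features(g, cell=config.cell, n_bins=config.n_bins, block=config.block)
        )
    return np.asarray(feats)


def train_detector(
    pos_snips, neg_snips, config: DetectorConfig | None = None, seed: int = 0
) -> DetectorModel:
    """Train the staged cascade on positive/negative gray or RGB snips.

    Each stage is an AdaBoost ensemble of depth-1 decision stumps whose pass
    threshold is set to retain at least ``stage_tpr`` of the positives;
    negatives still passing feed the next stage.  Training stops when the
    negatives are exhausted or ``n_stages`` is reached.  Deterministic given
    the seed.
    """
    config = config or DetectorConfig()
    pos_snips = list(pos_snips)
    neg_snips = list(neg_snips)
    if not pos_snips:
        raise ValueError("at least one positive snip is required")
    if not neg_snips:
        raise ValueError("at least one negative snip is required")
    X_pos = _snip_matrix(pos_snips, config)
    X_neg = _snip_matrix(neg_snips, config)
    stages: list = []
    rng_base = int(seed) % (2**31 - 1)
    for i in range(config.n_stages):
        if X_neg.shape[0] == 0:
            break
        X = np.vstack([X_pos, X_neg])
        y = np.concatenate([np.ones(len(X_pos)), np.zeros(len(X_neg))])
        clf = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1, random_state=rng_base + i),
            n_estimators=config.n_estimators,
            random_state=rng_base + i,
        )
        clf.fit(X, y)
        scores_pos = clf.decision_function(X_pos)
        # pass threshold: keep at least stage_tpr of positives, backed off by
        # a margin so near-boundary positives in unseen data still pass
        thr = float(np.quantile(scores_pos, 1.0 - config.stage_tpr))
        thr -= 0.5 * float(np.std(scores_pos)) + 1e-9
        scores_neg = clf.decision_function(X_neg)
        passed = scores_neg >= thr
        stages.append((clf, thr))
        X_neg = X_neg[passed]
        if passed.mean() <= 1.0 - config.stage_fpr and X_neg.shape[0] == 0:
            break
    return DetectorModel(config=config, stages=stages, seed=int(seed))


def _compile_stage(clf: AdaBoostClassifier):
    """Extract stump parameters so a stage can be scored with pure numpy.

    Returns ``(feat, split, left, right, wsum)`` where the stage score of a
    sample is ``sum_t w_t * s_t / wsum`` with ``s_t`` the +-1 vote of stump
    ``t`` (left vote when feature <= split).  Matches
    ``AdaBoostClassifier.decision_function`` for binary problems.
    """
    feats, splits, lefts, rights, ws = [], [], [], [], []
    for tree, w in zip(clf.estimators_, clf.estimator_weights_):
        if w == 0:
            continue
        t = tree.tree_
        if t.node_count == 1:  # degenerate stump: constant vote
            cls = int(np.argmax(t.value[0]))
            feats.append(0)
            splits.append(np.inf)  # everything goes left
            lefts.append(2 * cls - 1)
            rights.append(2 * cls - 1)
        else:
            feats.append(int(t.feature[0]))
            splits.append(float(t.threshold[0]))
            lefts.append(2 * int(np.argmax(t.value[1])) - 1)
            rights.append(2 * int(np.argmax(t.value[2])) - 1)
        ws.append(float(w))
    w_arr = np.asarray(ws)
    return (
        np.asarray(feats, dtype=int),
        np.asarray(splits),
        np.asarray(lefts, dtype=float) * w_arr,
        np.asarray(rights, dtype=float) * w_arr,
        # each binary vote counts double in sklearn's decision_function
        float(w_arr.sum()) / 2.0,
    )


def _cascade_pass(
    model: DetectorModel, X: np.ndarray, return_scores: bool = False
):
    """Boolean mask of rows surviving every cascade stage.

    With ``return_scores`` also returns each surviving row's margin over the
    final stage's threshold (a confidence used for hit grouping).
    """
    alive = np.ones(X.shape[0], dtype=bool)
    margin = np.zeros(X.shape[0], dtype=float)
    for clf, thr in model.stages:
        if not alive.any():
            break
        scores = clf.decision_function(X[alive])
        idx = np.nonzero(alive)[0]
        margin[idx] = scores - thr
        alive[idx[scores < thr]] = False
    if return_scores:
        return alive, margin
    return alive


def _pyramid_scales(config: DetectorConfig) -> list[float]:
    """Scales s such that the effective window (window * s) spans the
    configured fruit extent range."""
    scales = []
    s = config.min_window / config.window
    while config.window * s <= config.max_window:
        scales.append(s)
        s *= config.scale_step
    return scales


def detect_fruit(
    raster: np.ndarray, model: DetectorModel, merge_threshold: int | None = None
) -> list[BoundingBox]:
    """Multi-scale sliding-window detection with neighbor-count merging.

    Raw window hits at every pyramid level are grouped by overlap
    (IoU > ``merge_iou`` with the group's running mean box); groups with
    fewer than ``merge_threshold`` raw hits are discarded and survivors are
    reported as the mean box of their group, clipped to the raster.
    """
    cfg = model.config
    if merge_threshold is None:
        merge_threshold = cfg.merge_threshold
    gray = _to_gray(raster)
    rows, cols = gray.shape
    if rows < cfg.window or cols < cfg.window:
        return []
    ncells_win = cfg.window // cfg.cell
    nblk_win = ncells_win - cfg.block + 1
    nch = cfg.block * cfg.block * cfg.n_bins
    compiled = model.compiled_stages()
    offsets = [
        (oy, ox)
        for oy in range(0, cfg.cell, cfg.stride)
        for ox in range(0, cfg.cell, cfg.stride)
    ]

    raw: list[tuple[float, float, float, float, float]] = []
    for s in _pyramid_scales(cfg):
        h, w = int(round(rows / s)), int(round(cols / s))
        if h < cfg.window or w < cfg.window:
            continue
        img = gray if abs(s - 1.0) < 1e-9 else _sk_resize(
            gray, (h, w), anti_aliasing=s > 1.0, preserve_range=True
        )
        # edge-replicate padding so fruit near the frame border still get a
        # fully-contained window (the training margin is ~6% of the window)
        pad = 2 * cfg.cell
        img = np.pad(img, pad, mode="edge")
        for oy, ox in offsets:
            sub = img[oy:, ox:]
            if sub.shape[0] < cfg.window or sub.shape[1] < cfg.window:
                continue
            cells = hog_cell_histograms(sub, cell=cfg.cell, n_bins=cfg.n_bins)
            blocks = _block_normalize(cells, block=cfg.block)
            nby, nbx = blocks.shape[:2]
            nwy, nwx = nby - nblk_win + 1, nbx - nblk_win + 1
            if nwy <= 0 or nwx <= 0:
                continue
            alive = np.ones((nwy, nwx), dtype=bool)
            margin = np.zeros((nwy, nwx), dtype=float)
            for (feat, split, left_w, right_w, wsum), thr in compiled:
                if not alive.any():
                    break
                score = np.zeros((nwy, nwx), dtype=float)
                for t in range(feat.size):
                    f = int(feat[t])
                    by, rem = divmod(f, nblk_win * nch)
                    bx, ch = divmod(rem, nch)
                    vals = blocks[by : by + nwy, bx : bx + nwx, ch]
                    score += np.where(vals <= split[t], left_w[t], right_w[t])
                score /= wsum
                margin = score - thr
                alive &= score >= thr
            for wy, wx in zip(*np.nonzero(alive)):
                x0 = (ox + wx * cfg.cell - pad) * s
                y0 = (oy + wy * cfg.cell - pad) * s
                raw.append(
                    (x0, y0, x0 + cfg.window * s, y0 + cfg.window * s,
                     margin[wy, wx])
                )

    # score-seeded grouping: the strongest remaining hit seeds a group and
    # absorbs every overlapping hit; the reported box is the score-weighted
    # mean of the group's members
    hits = np.asarray(raw, dtype=float).reshape(-1, 5)
    order = np.argsort(-hits[:, 4])
    hits = hits[order]
    taken = np.zeros(len(hits), dtype=bool)
    out: list[BoundingBox] = []
    for i in range(len(hits)):
        if taken[i]:
            continue
        seed = hits[i, :4]
        members = [i]
        taken[i] = True
        for j in range(i + 1, len(hits)):
            if not taken[j] and _iou_arr(seed, hits[j, :4]) > cfg.merge_iou:
                members.append(j)
                taken[j] = True
        if len(members) < merge_threshold:
            continue
        grp = hits[members]
        w = np.maximum(grp[:, 4], 1e-6)
        mean_box = (grp[:, :4] * w[:, None]).sum(axis=0) / w.sum()
        # windows carry a training margin around the fruit; shrink to the
        # expected fruit extent
        mcx = (mean_box[0] + mean_box[2]) / 2.0
        mcy = (mean_box[1] + mean_box[3]) / 2.0
        half = (mean_box[2] - mean_box[0]) / 2.0 * cfg.box_shrink
        mean_box = np.array([mcx - half, mcy - half, mcx + half, mcy + half])
        x0, y0, x1, y1 = np.round(mean_box).astype(int)
        box = BoundingBox(
            int(x0), int(y0), int(max(x1, x0 + 1)), int(max(y1, y0 + 1))
        ).clip(cols, rows)
        out.append(box)
    return out


def _iou_arr(a: np.ndarray, b: np.ndarray) -> float:
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    if ix1 <= ix0 or iy1 <= iy0:
        return 0.0
    inter = (ix1 - ix0) * (iy1 - iy0)
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return float(inter / (area_a + area_b - inter))


def save_model(model: DetectorModel, path) -> None:
    """Serialise a trained detector (versioned header + parameters)."""
    with open(path, "wb") as fh:
        pickle.dump({"format": MODEL_FORMAT, "model": model}, fh)


def load_model(path) -> DetectorModel:
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"unrecognised model format: {payload.get('format')!r}")
    return payload["model"]
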