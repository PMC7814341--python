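"""Multiview segmentation + score-regression model at desk scale.

The model mimics a reading clinician's axial-primary workflow: every voxel is
described by a 3x3 axial window plus 3x3 coronal and sagittal context windows
resampled through the same spatial location, its normalised (z, y, x)
position, and smooth encodings of its HU against the clinical density
thresholds. A shared single-hidden-layer encoder feeds two heads:

* a per-pixel 6-class softmax head (background, LM, LAD, LCX, RCA,
  non-coronary calcification) trained with cross-entropy, and
* a per-slice regression head that sum-pools the hidden features of
  supra-threshold pixels and maps them linearly (no bias, so empty slices
  predict exactly zero) to the slice's per-vessel Agatston contributions,
  trained with mean absolute error.

Training is joint (cross-entropy + lambda * MAE) with Adam in plain numpy;
all randomness flows from the config seed, so a fixed (data, config, seed)
triple reproduces parameters bit-for-bit. At prediction time voxels below
the 130 HU scoring threshold are forced to background, so only
supra-threshold voxels are ever classified.

Class imbalance is handled by foreground-biased sampling: every
supra-threshold voxel enters the training set, together with a seeded random
subset of background voxels.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core_io import (
    CORONARY_LABELS,
    VESSEL_NAMES,
    CtVolume,
    VesselLabelMask,
    check_congruent,
)
from .scoring import ScoringConfig, agatston_weight, extract_lesions

N_CLASSES = 6
_THRESHOLDS = (130.0, 200.0, 300.0, 400.0)
_HU_SCALE = 1000.0
_POOL_SCALE = 32.0  # typical supra-threshold pixel count per slice


class TrainingError(RuntimeError):
    pass


@dataclass
class MvscConfig:
    """Model and training hyperparameters.

    ``lambda_reg`` balances the regression MAE against the segmentation
    cross-entropy (small by default so segmentation dominates early);
    ``score_scale`` puts Agatston targets on an O(1) scale for the MAE head;
    ``bg_per_fg`` is the number of background voxels sampled per foreground
    (supra-threshold) voxel.
    """

    hidden: int = 48
    epochs: int = 300
    lr: float = 0.02
    lambda_reg: float = 0.01
    score_scale: float = 100.0
    bg_per_fg: float = 1.0
    hu_threshold: float = 130.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden, self.epochs) < 1 or min(self.lr, self.lambda_reg,
                                                    self.score_scale) <= 0:
            raise ValueError("all MvscConfig numeric fields must be positive")


@dataclass
class MultiviewSample:
    """One axial slice with its coronal/sagittal context planes and targets."""

    slice_index: int
    axial_patch: np.ndarray  # (Y, X) HU
    coronal_context: np.ndarray  # (Z, X) HU through the slice-centre row
    sagittal_context: np.ndarray  # (Z, Y) HU through the slice-centre column
    target_mask: np.ndarray  # (Y, X) labels 0..5
    target_scores: np.ndarray  # (4,) per-vessel AS contribution of this slice


def per_slice_scores(vol: CtVolume, mask: VesselLabelMask,
                     cfg: ScoringConfig | None = None) -> np.ndarray:
    """(n_slices, 4) per-vessel Agatston contributions of each axial slice."""
    lesions = extract_lesions(vol, mask, cfg or ScoringConfig())
    out = np.zeros((vol.shape[0], 4))
    for lesion in lesions:
        if lesion.vessel in CORONARY_LABELS:
            out[lesion.slice_index, lesion.vessel - 1] += (
                lesion.area_mm2 * agatston_weight(lesion.peak_hu)
            )
    return out


def build_samples(vol: CtVolume, mask: VesselLabelMask,
                  cert_scores: np.ndarray | None = None) -> list[MultiviewSample]:
    """One multiview sample per axial slice.

    Context planes are nearest-neighbour extractions through the in-plane
    centre of the slice. ``cert_scores`` may supply precomputed per-slice
    per-vessel AS targets; otherwise they are derived from (vol, mask).
    """
    check_congruent(vol, mask)
    if cert_scores is None:
        cert_scores = per_slice_scores(vol, mask)
    if cert_scores.shape != (vol.shape[0], 4):
        raise ValueError(
            f"cert_scores must have shape ({vol.shape[0]}, 4), "
            f"got {cert_scores.shape}"
        )
    y_mid, x_mid = vol.shape[1] // 2, vol.shape[2] // 2
    samples = []
    for z in range(vol.shape[0]):
        samples.append(MultiviewSample(
            slice_index=z,
            axial_patch=vol.voxels[z],
            coronal_context=vol.voxels[:, y_mid, :],
            sagittal_context=vol.voxels[:, :, x_mid],
            target_mask=mask.labels[z],
            target_scores=cert_scores[z],
        ))
    return samples


# ---------------------------------------------------------------------------
# Featurisation

N_ATLAS = 6
N_FEATURES = 27 + 3 + len(_THRESHOLDS) + N_ATLAS


def _atlas_features(vol: CtVolume, zz: np.ndarray, yy: np.ndarray,
                    xx: np.ndarray) -> np.ndarray:
    """Vessel-territory prior: proximity to each coronary centerline and to
    the aortic root of the package's fixed cardiac atlas, scaled to the
    volume extent. Encoded as exp(-d/4 mm) so it saturates away from the
    vessels."""
    from .phantom import (LAD, LCX, LM, RCA, PhantomSpec, aortic_root_geometry,
                          vessel_centerline)

    spec = PhantomSpec(shape=vol.shape, spacing=vol.spacing)
    world = np.stack([zz * vol.spacing[0], yy * vol.spacing[1],
                      xx * vol.spacing[2]], axis=1)
    cols = []
    for vessel in (LM, LAD, LCX, RCA):
        pts = vessel_centerline(spec, vessel)
        d = np.sqrt(((world[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        cols.append(np.exp(-d.min(axis=1) / 2.0))
    root = aortic_root_geometry(spec)
    cy, cx = root["center_yx"]
    z_lo, z_hi = (s * vol.spacing[0] for s in root["slices"])
    dz_out = np.maximum(0.0, np.maximum(z_lo - world[:, 0], world[:, 0] - z_hi))
    d_inplane = np.sqrt((world[:, 1] - cy) ** 2 + (world[:, 2] - cx) ** 2)
    d_root = np.sqrt(d_inplane ** 2 + dz_out ** 2)
    cols.append(np.exp(-d_root / 4.0))
    # sharp in-root membership: separates aortic-sinus calcification from
    # coronary ostium lesions just outside the root wall
    inside = 1.0 / (1.0 + np.exp((d_inplane - root["radius_mm"]) / 0.5))
    inside[dz_out > 0] = 0.0
    cols.append(inside)
    return np.stack(cols, axis=1)


def _featurize(vol: CtVolume, zz: np.ndarray, yy: np.ndarray, xx: np.ndarray
               ) -> np.ndarray:
    """Multiview feature vectors for the voxels at (zz, yy, xx)."""
    padded = np.pad(vol.voxels, 1, mode="edge")
    z, y, x = zz + 1, yy + 1, xx + 1
    cols = []
    # axial 3x3 (fixed z), coronal 3x3 (fixed y), sagittal 3x3 (fixed x)
    for da in (-1, 0, 1):
        for db in (-1, 0, 1):
            cols.append(padded[z, y + da, x + db])
    for da in (-1, 0, 1):
        for db in (-1, 0, 1):
            cols.append(padded[z + da, y, x + db])
    for da in (-1, 0, 1):
        for db in (-1, 0, 1):
            cols.append(padded[z + da, y + db, x])
    feats = np.stack(cols, axis=1) / _HU_SCALE
    nz, ny, nx = vol.shape
    coords = np.stack([zz / max(nz - 1, 1), yy / max(ny - 1, 1),
                       xx / max(nx - 1, 1)], axis=1)
    hu = vol.voxels[zz, yy, xx]
    thresh = np.stack([1.0 / (1.0 + np.exp(-(hu - t) / 20.0))
                       for t in _THRESHOLDS], axis=1)
    atlas = _atlas_features(vol, zz, yy, xx)
    return np.concatenate([feats, coords, thresh, atlas], axis=1)


# ---------------------------------------------------------------------------
# Model

@dataclass
class TrainedModel:
    """Learned parameters plus the config and training-data fingerprint."""

    params: dict[str, np.ndarray]
    config: MvscConfig
    data_fingerprint: str
    train_log: list[dict] = field(default_factory=list)

    def save(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        np.savez(out_dir / "params.npz", **self.params)
        (out_dir / "config.json").write_text(json.dumps(
            {"config": asdict(self.config),
             "data_fingerprint": self.data_fingerprint}, indent=2))
        with open(out_dir / "train_log.jsonl", "w") as fh:
            for entry in self.train_log:
                fh.write(json.dumps(entry) + "\n")
        return out_dir

    @classmethod
    def load(cls, out_dir: str | Path) -> "TrainedModel":
        out_dir = Path(out_dir)
        with np.load(out_dir / "params.npz") as npz:
            params = {k: npz[k].copy() for k in npz.files}
        meta = json.loads((out_dir / "config.json").read_text())
        log_path = out_dir / "train_log.jsonl"
        log = []
        if log_path.exists():
            log = [json.loads(line) for line in log_path.read_text().splitlines()]
        return cls(params=params, config=MvscConfig(**meta["config"]),
                   data_fingerprint=meta["data_fingerprint"], train_log=log)

    # forward pieces -------------------------------------------------------
    def _hidden(self, feats: np.ndarray) -> np.ndarray:
        return np.tanh(feats @ self.params["W1"] + self.params["b1"])

    def _logits(self, hidden: np.ndarray) -> np.ndarray:
        return hidden @ self.params["Wseg"] + self.params["bseg"]


def _init_params(cfg: MvscConfig, rng: np.random.Generator) -> dict:
    scale1 = np.sqrt(2.0 / N_FEATURES)
    scale2 = np.sqrt(2.0 / cfg.hidden)
    return {
        "W1": rng.normal(0.0, scale1, (N_FEATURES, cfg.hidden)),
        "b1": np.zeros(cfg.hidden),
        "Wseg": rng.normal(0.0, scale2, (cfg.hidden, N_CLASSES)),
        "bseg": np.zeros(N_CLASSES),
        "Wreg": np.zeros((cfg.hidden, 4)),
    }


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _fingerprint(arrays: list[np.ndarray]) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def _gather_training_set(cohort, cfg: MvscConfig, rng: np.random.Generator):
    """Foreground-complete, background-subsampled pixel set plus slice groups.

    Returns (features, labels, slice_groups) where slice_groups maps each
    (case, slice) with supra-threshold pixels to its row indices in the
    feature matrix and its 4-vector score target.
    """
    feats_list, labels_list = [], []
    groups: list[tuple[np.ndarray, np.ndarray]] = []
    offset = 0
    for case in cohort:
        vol, mask = case.volume, case.mask
        targets = per_slice_scores(vol, mask)
        supra = vol.voxels >= cfg.hu_threshold
        zz, yy, xx = np.nonzero(supra)
        n_fg = zz.size
        bg_pool = np.nonzero(~supra)
        n_bg = min(int(round(cfg.bg_per_fg * max(n_fg, 50))), bg_pool[0].size)
        pick = rng.choice(bg_pool[0].size, size=n_bg, replace=False)
        zzb, yyb, xxb = (bg_pool[0][pick], bg_pool[1][pick], bg_pool[2][pick])
        zall = np.concatenate([zz, zzb])
        yall = np.concatenate([yy, yyb])
        xall = np.concatenate([xx, xxb])
        feats = _featurize(vol, zall, yall, xall)
        labels = np.concatenate([mask.labels[zz, yy, xx],
                                 np.zeros(n_bg, dtype=np.int64)])
        feats_list.append(feats)
        labels_list.append(labels)
        for z in np.unique(zz):
            rows = offset + np.nonzero(zz == z)[0]
            groups.append((rows, targets[z] / cfg.score_scale))
        offset += zall.size
    X = np.concatenate(feats_list)
    y = np.concatenate(labels_list)
    return X, y, groups


def train(cohort, cfg: MvscConfig | None = None) -> TrainedModel:
    """Jointly train segmentation and regression heads on a phantom cohort.

    ``cohort`` is a sequence of objects with ``.volume`` and ``.mask``
    attributes (e.g. :class:`cacskit.phantom.PhantomCase`). Deterministic for
    a fixed (cohort, config, seed).
    """
    cfg = cfg or MvscConfig()
    cohort = list(cohort)
    if not cohort:
        raise TrainingError("cannot train on an empty cohort")
    rng = np.random.default_rng(cfg.seed)
    X, y, groups = _gather_training_set(cohort, cfg, rng)
    if X.shape[0] == 0:
        raise TrainingError("training set is empty")
    params = _init_params(cfg, rng)
    model = TrainedModel(
        params=params, config=cfg,
        data_fingerprint=_fingerprint([X, y.astype(np.float64)]),
    )
    onehot = np.zeros((y.size, N_CLASSES))
    onehot[np.arange(y.size), y] = 1.0

    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(val) for k, val in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    n_pix = X.shape[0]
    n_slices = max(len(groups), 1)

    for epoch in range(1, cfg.epochs + 1):
        hidden = np.tanh(X @ params["W1"] + params["b1"])
        logits = hidden @ params["Wseg"] + params["bseg"]
        probs = _softmax(logits)
        ce = -np.mean(np.log(probs[np.arange(n_pix), y] + 1e-12))

        d_logits = (probs - onehot) / n_pix
        g_Wseg = hidden.T @ d_logits
        g_bseg = d_logits.sum(axis=0)
        d_hidden = d_logits @ params["Wseg"].T

        mae = 0.0
        g_Wreg = np.zeros_like(params["Wreg"])
        for rows, target in groups:
            pooled = hidden[rows].sum(axis=0) / _POOL_SCALE
            pred = pooled @ params["Wreg"]
            err = pred - target
            mae += np.abs(err).sum()
            sign = np.sign(err)
            g_Wreg += np.outer(pooled, sign) * (cfg.lambda_reg / n_slices)
            d_hidden[rows] += (params["Wreg"] @ sign) * (
                cfg.lambda_reg / (n_slices * _POOL_SCALE))
        mae /= n_slices

        d_pre = d_hidden * (1.0 - hidden ** 2)
        grads = {
            "W1": X.T @ d_pre,
            "b1": d_pre.sum(axis=0),
            "Wseg": g_Wseg,
            "bseg": g_bseg,
            "Wreg": g_Wreg,
        }
        loss = ce + cfg.lambda_reg * mae
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite loss at epoch {epoch}")
        # linear decay lets the MAE head settle (its gradient never vanishes)
        lr_t = cfg.lr * max(0.02, 1.0 - (epoch - 1) / cfg.epochs)
        for k in params:
            m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
            v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
            m_hat = m[k] / (1 - beta1 ** epoch)
            v_hat = v[k] / (1 - beta2 ** epoch)
            params[k] -= lr_t * m_hat / (np.sqrt(v_hat) + eps)
        if epoch == 1 or epoch % 25 == 0 or epoch == cfg.epochs:
            model.train_log.append(
                {"epoch": epoch, "loss": float(loss), "ce": float(ce),
                 "mae_scaled": float(mae)})
    return model


def predict_mask(model: TrainedModel, vol: CtVolume) -> VesselLabelMask:
    """Per-voxel argmax labels; voxels below the HU threshold are background."""
    labels = np.zeros(vol.shape, dtype=np.int64)
    supra = vol.voxels >= model.config.hu_threshold
    zz, yy, xx = np.nonzero(supra)
    if zz.size:
        feats = _featurize(vol, zz, yy, xx)
        logits = model._logits(model._hidden(feats))
        labels[zz, yy, xx] = np.argmax(logits, axis=1)
    return VesselLabelMask(labels=labels, spacing=vol.spacing, origin=vol.origin)


def predict_scores(model: TrainedModel, vol: CtVolume) -> dict[str, float]:
    """Direct per-vessel Agatston estimates from the regression head.

    Per-slice predictions are clipped at zero and summed over slices; the
    result is always finite and non-negative.
    """
    supra = vol.voxels >= model.config.hu_threshold
    zz, yy, xx = np.nonzero(supra)
    totals = np.zeros(4)
    if zz.size:
        feats = _featurize(vol, zz, yy, xx)
        hidden = model._hidden(feats)
        for z in np.unique(zz):
            pooled = hidden[zz == z].sum(axis=0) / _POOL_SCALE
            pred = pooled @ model.params["Wreg"] * model.config.score_scale
            totals += np.clip(pred, 0.0, None)
    scores = {VESSEL_NAMES[v]: float(totals[v - 1]) for v in CORONARY_LABELS}
    scores["Total"] = float(totals.sum())
    return scores
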