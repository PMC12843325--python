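"""CNN recognition harness: training protocols, rank-1 evaluation,
cross-view matrices and covariate reports.

The network follows the classic two-block silhouette-template CNN
(18 7x7 filters, then 45 5x5, each with batch-norm/ReLU/2x2 max-pool,
then a 1024-unit fully connected layer with dropout 0.5 and a softmax
classifier).  Two protocols are supported:

* ``loto`` — leave-one-trial-out closed-set classification: early trials
  train, late trials test, identities shared.  AdamW, lr 1e-3, weight
  decay 1e-4, cosine schedule with 5-epoch warm-up, early stopping with
  patience 10.
* ``gallery_probe`` — unseen-identity identification: the classifier is
  trained on a disjoint subject set with cross-entropy/Adam, then each
  probe template is matched to the nearest gallery template in the
  1024-d penultimate embedding space under cosine distance.

The same training configuration is reused verbatim across the line-based,
joint-based and silhouette-energy inputs so that observed differences are
attributable to the representations alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import nn
from .io import GaitTemplate, RunConfig
from .simulate import simulate_silhouettes
from .templates import compute_gei, compute_gsi

__all__ = [
    "TrainConfig",
    "GaitCNN",
    "IdentificationReport",
    "render_templates",
    "train",
    "evaluate_loto",
    "evaluate_gallery_probe",
    "summarize_matrix",
    "covariate_report",
]


@dataclass
class TrainConfig:
    protocol: str = "loto"  # loto | gallery_probe
    lr: float = 1e-3
    weight_decay: float = 1e-4  # decoupled (AdamW); 0 under plain Adam
    batch_size: int = 32
    max_epochs: int = 50
    patience: int = 10
    warmup_epochs: int = 5
    dropout: float = 0.5

    def __post_init__(self) -> None:
        if self.protocol not in ("loto", "gallery_probe"):
            raise ValueError("protocol must be 'loto' or 'gallery_probe'")


class GaitCNN:
    """Two-convolutional-block template classifier with a 1024-d embedding."""

    def __init__(self, n_classes: int, input_hw=(120, 80), dropout: float = 0.5, seed: int = 0):
        h, w = input_hw
        rng = np.random.default_rng(seed)
        h1, w1 = (h - 6) // 2, (w - 6) // 2  # conv 7x7 valid + pool
        h2, w2 = (h1 - 4) // 2, (w1 - 4) // 2  # conv 5x5 valid + pool
        fc_in = 45 * h2 * w2
        self.net = nn.Sequential(
            nn.Conv2d(1, 18, 7, rng),
            nn.BatchNorm2d(18),
            nn.ReLU(),
            nn.MaxPool2x2(),
            nn.Conv2d(18, 45, 5, rng),
            nn.BatchNorm2d(45),
            nn.ReLU(),
            nn.MaxPool2x2(),
            nn.Flatten(),
            nn.Linear(fc_in, 1024, rng),
            nn.ReLU(),
            nn.Dropout(dropout, rng),
            nn.Linear(1024, n_classes, rng),
        )
        self._embed_until = 11  # through the post-FC ReLU, before dropout
        self.n_classes = n_classes
        self.input_hw = (h, w)

    def logits(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(X, train)

    def predict(self, X: np.ndarray, batch: int = 64) -> np.ndarray:
        out = [
            np.argmax(self.net.forward(X[i : i + batch], False), axis=1)
            for i in range(0, len(X), batch)
        ]
        return np.concatenate(out)

    def embed(self, X: np.ndarray, batch: int = 64) -> np.ndarray:
        """1024-d penultimate activations (dropout inactive)."""
        out = [
            self.net.forward_until(X[i : i + batch], self._embed_until, False)
            for i in range(0, len(X), batch)
        ]
        return np.concatenate(out)

    def state(self):
        return [p.value.copy() for p in self.net.params()]

    def load_state(self, state):
        for p, v in zip(self.net.params(), state):
            p.value[...] = v


def _as_pixel_stack(templates: Sequence) -> np.ndarray:
    pix = [t.pixels if isinstance(t, GaitTemplate) else np.asarray(t) for t in templates]
    return np.stack(pix).astype(np.float32)[:, None, :, :]


def render_templates(manifest: pd.DataFrame, cfg: RunConfig, body_width: float = 0.10) -> pd.DataFrame:
    """Add a ``template`` column to a cohort manifest.

    Skeletal variants run the full template pipeline; the ``gei`` variant
    renders matching synthetic silhouettes first and averages them.
    Requires an in-memory ``sequence`` column (or a ``path`` column of
    JSON-lines files, loaded on demand).
    """
    from .io import read_sequence

    out = manifest.copy()
    templates = []
    for _, row in out.iterrows():
        seq = row["sequence"] if "sequence" in out.columns else read_sequence(row["path"])
        if cfg.variant == "gei":
            templates.append(
                compute_gei(simulate_silhouettes(seq, body_width), cfg.canvas_w, cfg.canvas_h,
                            cfg.height_margin, align=False)
            )
        else:
            templates.append(compute_gsi(seq, cfg))
    out["template"] = templates
    return out


def train(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    seed: int = 0,
    validation: Optional[tuple] = None,
    n_classes: Optional[int] = None,
):
    """Train a template classifier; returns (model, per-epoch log).

    ``y`` holds integer class labels.  With a validation set, early
    stopping restores the weights of the best validation epoch.
    """
    y = np.asarray(y)
    classes = int(n_classes or (y.max() + 1))
    if len(np.unique(y)) < 2:
        raise ValueError("training needs at least 2 identities")
    X = np.asarray(X, dtype=np.float32)
    model = GaitCNN(classes, input_hw=X.shape[2:], dropout=cfg.dropout, seed=seed)
    params = model.net.params()
    wd = cfg.weight_decay if cfg.protocol == "loto" else 0.0
    opt = nn.AdamW(params, lr=cfg.lr, weight_decay=wd)
    rng = np.random.default_rng(seed + 1)

    log: List[dict] = []
    best_metric, best_state, since_best = -np.inf, None, 0
    n = len(X)
    for epoch in range(cfg.max_epochs):
        if cfg.protocol == "loto":
            opt.lr = nn.warmup_cosine_lr(epoch, cfg.max_epochs, cfg.lr, cfg.warmup_epochs)
        order = rng.permutation(n)
        losses, correct = [], 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            model.net.zero_grad()
            logits = model.logits(X[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
            model.net.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((np.argmax(logits, axis=1) == y[idx]).sum())
        entry = {"epoch": epoch, "lr": opt.lr, "loss": float(np.mean(losses)),
                 "train_acc": 100.0 * correct / n}
        if validation is not None:
            Xv, yv = validation
            val_acc = 100.0 * float((model.predict(np.asarray(Xv, np.float32)) == yv).mean())
            entry["val_acc"] = val_acc
            metric = val_acc
        else:
            metric = -entry["loss"]
        log.append(entry)
        if metric > best_metric:
            best_metric, best_state, since_best = metric, model.state(), 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    if best_state is not None:
        model.load_state(best_state)
    return model, log


# ---------------------------------------------------------------------------
# protocols


def _labels(subjects: Sequence[str]):
    uniq = sorted(set(subjects))
    index = {s: i for i, s in enumerate(uniq)}
    return np.array([index[s] for s in subjects]), uniq


def split_loto(manifest: pd.DataFrame, test_trials: Sequence[str] = ("09", "10")):
    """Trials are split by label: listed trials test, the rest train."""
    test_trials = {str(t) for t in test_trials}
    is_test = manifest["trial"].astype(str).isin(test_trials)
    if not is_test.any():
        raise ValueError(f"no test trials {sorted(test_trials)} present in manifest")
    return manifest[~is_test], manifest[is_test]


def run_loto(
    manifest: pd.DataFrame,
    cfg: TrainConfig,
    seed: int = 0,
    test_trials: Sequence[str] = ("09", "10"),
    val_trials: Sequence[str] = ("08",),
):
    """LOTO protocol on a rendered manifest (needs a ``template`` column).

    Training uses all non-test trials except ``val_trials``, which form the
    early-stopping validation split (the last training trial per subject).
    Returns (model, log, held-out accuracy %).
    """
    train_df, test_df = split_loto(manifest, test_trials)
    val_set = {str(t) for t in val_trials}
    is_val = train_df["trial"].astype(str).isin(val_set)
    fit_df, val_df = train_df[~is_val], train_df[is_val]

    y_all, subjects = _labels(manifest["subject"])
    lab = {s: i for i, s in enumerate(subjects)}
    Xf = _as_pixel_stack(fit_df["template"].tolist())
    yf = np.array([lab[s] for s in fit_df["subject"]])
    Xv = _as_pixel_stack(val_df["template"].tolist()) if len(val_df) else None
    yv = np.array([lab[s] for s in val_df["subject"]]) if len(val_df) else None
    validation = (Xv, yv) if Xv is not None else None
    model, log = train(Xf, yf, cfg, seed=seed, validation=validation, n_classes=len(subjects))
    acc = evaluate_loto(model, test_df, labels=lab)
    return model, log, acc


def evaluate_loto(model: GaitCNN, test_df: pd.DataFrame, labels: Dict[str, int]) -> float:
    """Closed-set softmax accuracy (%) on held-out trials."""
    if len(test_df) == 0:
        raise ValueError("no held-out test trials to evaluate")
    X = _as_pixel_stack(test_df["template"].tolist())
    y = np.array([labels[s] for s in test_df["subject"]])
    return 100.0 * float((model.predict(X) == y).mean())


def _cosine_rank1(gal_emb, gal_ids, probe_emb, probe_ids) -> float:
    gn = gal_emb / np.maximum(np.linalg.norm(gal_emb, axis=1, keepdims=True), 1e-12)
    pn = probe_emb / np.maximum(np.linalg.norm(probe_emb, axis=1, keepdims=True), 1e-12)
    sim = pn @ gn.T
    # argmax picks the lowest gallery index on exact ties
    nearest = np.argmax(sim, axis=1)
    return 100.0 * float(np.mean(np.asarray(gal_ids)[nearest] == np.asarray(probe_ids)))


@dataclass
class IdentificationReport:
    """Rank-1 results as gallery-view x probe-view x covariate cells."""

    views: List[float]
    cross_view: Dict[str, np.ndarray]  # covariate -> (n_views, n_views) %
    counts: Dict[str, np.ndarray] = field(default_factory=dict)

    def matrix(self, covariate: str = "NM") -> pd.DataFrame:
        return pd.DataFrame(self.cross_view[covariate], index=self.views, columns=self.views)

    def same_view_mean(self, covariate: str = "NM") -> float:
        return float(np.diagonal(self.cross_view[covariate]).mean())

    def summary(self, covariate: str = "NM") -> dict:
        return summarize_matrix(self.cross_view[covariate])

    def degradation(self) -> dict:
        """Per-condition same-view mean minus the NM same-view mean (pp)."""
        nm = self.same_view_mean("NM")
        return {
            c: self.same_view_mean(c) - nm for c in self.cross_view if c != "NM"
        }

    def to_dict(self) -> dict:
        return {
            "views": self.views,
            "cross_view": {c: m.tolist() for c, m in self.cross_view.items()},
            "summaries": {c: {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                              for k, v in self.summary(c).items()}
                          for c in self.cross_view},
            "degradation_pp": self.degradation(),
        }


def evaluate_gallery_probe(
    gallery: pd.DataFrame, probe: pd.DataFrame, model: GaitCNN
) -> IdentificationReport:
    """Unseen-identity rank-1 identification.

    Both frames need columns subject, view_deg, covariate, template.  Every
    probe is assigned the identity of its nearest gallery embedding under
    cosine distance; rank-1 is tabulated per (gallery view, probe view,
    covariate).  Gallery templates are expected to be NM.
    """
    missing = sorted(set(probe["subject"]) - set(gallery["subject"]))
    if missing:
        raise ValueError(f"probe identities missing from gallery: {missing}")
    views = sorted(set(gallery["view_deg"]) | set(probe["view_deg"]))
    g_emb = model.embed(_as_pixel_stack(gallery["template"].tolist()))
    p_emb = model.embed(_as_pixel_stack(probe["template"].tolist()))
    gallery = gallery.reset_index(drop=True)
    probe = probe.reset_index(drop=True)

    report = IdentificationReport(views=views, cross_view={})
    for cond in sorted(set(probe["covariate"])):
        mat = np.full((len(views), len(views)), np.nan)
        cnt = np.zeros((len(views), len(views)), dtype=int)
        for gi, gv in enumerate(views):
            gmask = (gallery["view_deg"] == gv).to_numpy()
            if not gmask.any():
                continue
            for pi, pv in enumerate(views):
                pmask = ((probe["view_deg"] == pv) & (probe["covariate"] == cond)).to_numpy()
                if not pmask.any():
                    continue
                mat[gi, pi] = _cosine_rank1(
                    g_emb[gmask], gallery.loc[gmask, "subject"].to_numpy(),
                    p_emb[pmask], probe.loc[pmask, "subject"].to_numpy(),
                )
                cnt[gi, pi] = int(pmask.sum())
        report.cross_view[cond] = mat
        report.counts[cond] = cnt
    return report


# ---------------------------------------------------------------------------
# aggregation arithmetic


def summarize_matrix(matrix) -> dict:
    """Exact mean structure of a square view-by-view accuracy matrix:
    per-row and per-column means, diagonal mean, mean of column means and
    off-diagonal mean."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    off = ~np.eye(m.shape[0], dtype=bool)
    return {
        "row_means": m.mean(axis=1),
        "col_means": m.mean(axis=0),
        "diagonal_mean": float(np.diagonal(m).mean()),
        "mean_of_col_means": float(m.mean(axis=0).mean()),
        "off_diagonal_mean": float(m[off].mean()),
    }


def covariate_report(same_view_means: Dict[str, Dict[str, float]]) -> pd.DataFrame:
    """Covariate table from per-method same-view means.

    Input maps method name -> {"NM": %, "BG": %, "CL": %}.  Output columns:
    the three condition means, their overall mean, and each non-NM
    condition's degradation (condition minus NM, percentage points).
    """
    rows = {}
    for method, means in same_view_means.items():
        if "NM" not in means:
            raise ValueError(f"method {method!r} is missing the NM column")
        conds = list(means)
        row = dict(means)
        row["Mean"] = float(np.mean([means[c] for c in conds]))
        for c in conds:
            if c != "NM":
                row[f"deg_{c}"] = means[c] - means["NM"]
        rows[method] = row
    return pd.DataFrame(rows).T
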