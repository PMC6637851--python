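"""PLS regression (NIPALS) with LOO validation and field-model selection.

The regression couples the field matrix X (compounds × grid variables,
pretreated and BUW-scaled) to the activity vector y (pKi).  Components are
extracted with the NIPALS PLS1 algorithm; X and y are mean-centered
internally and no per-variable scaling is applied (BUW already set the
block variances).

Statistics follow the conventions customary in 3D-QSAR reporting:

* R² = 1 − SSres/SStot and fitting S = sqrt(SSres/(n − NC − 1)) on training;
* Q² = 1 − PRESS/Σ(y−ȳ)² with leave-one-out refits (the alive-variable set
  and BUW weights are frozen from the full training matrix; each fold only
  re-centers), S_LOO = sqrt(PRESS/n);
* external Rtest² = squared Pearson correlation between predicted and
  observed, S_test = sqrt(Σ(pred−obs)²/n_test);
* per-block contribution %S/%E from the variance of y explained by each
  component, split over blocks by the squared x-weights.

Model selection scans field subsets {S, E, SE} × component counts and keeps
the highest Q², breaking ties toward fewer components, then fewer fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import FieldMatrix, write_dx
from .io_dataset import ActivityTable

DEFAULT_FIELD_SETS: tuple[tuple[str, ...], ...] = (
    ("steric",), ("electrostatic",), ("steric", "electrostatic"))


@dataclass
class PLSModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray  # (p, nc), unit columns
    x_loadings: np.ndarray  # (p, nc)
    y_loadings: np.ndarray  # (nc,)
    score_ssq: np.ndarray  # (nc,) t_a' t_a
    coef: np.ndarray  # (p,) regression vector on centered X
    fitted: np.ndarray  # training predictions
    training_ids: list[str] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.y_mean + (X - self.x_mean) @ self.coef


def fit_pls(X: np.ndarray, y: np.ndarray, nc: int,
            training_ids: list[str] | None = None) -> PLSModel:
    """NIPALS PLS1 with ``nc`` latent components."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y row counts differ")
    if nc < 1 or nc > min(n - 1, p):
        raise ValueError(f"n_components must be in 1..{min(n - 1, p)}, got {nc}")
    if np.ptp(y) == 0:
        raise ValueError("constant response: PLS undefined")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    E = X - x_mean
    f = y - y_mean
    W = np.zeros((p, nc))
    P = np.zeros((p, nc))
    q = np.zeros(nc)
    ssq = np.zeros(nc)
    a = 0
    for a in range(nc):
        w = E.T @ f
        nw = np.linalg.norm(w)
        if nw < 1e-12:  # response variance exhausted
            nc = a
            break
        w /= nw
        t = E @ w
        tt = float(t @ t)
        if tt < 1e-12:
            nc = a
            break
        pa = E.T @ t / tt
        qa = float(f @ t) / tt
        E = E - np.outer(t, pa)
        f = f - qa * t
        W[:, a], P[:, a], q[a], ssq[a] = w, pa, qa, tt
    if nc == 0:
        raise ValueError("no PLS component could be extracted")
    W, P, q, ssq = W[:, :nc], P[:, :nc], q[:nc], ssq[:nc]
    coef = W @ np.linalg.solve(P.T @ W, q)
    model = PLSModel(nc, x_mean, y_mean, W, P, q, ssq, coef,
                     fitted=np.empty(0), training_ids=list(training_ids or []))
    model.fitted = model.predict(X)
    return model


def training_r2_s(y: np.ndarray, fitted: np.ndarray, nc: int) -> tuple[float, float]:
    y = np.asarray(y, dtype=float)
    ssres = float(np.sum((y - fitted) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ssres / sstot
    dof = max(len(y) - nc - 1, 1)
    return r2, float(np.sqrt(ssres / dof))


def loo_q2(X: np.ndarray, y: np.ndarray, nc: int) -> tuple[float, float]:
    """Leave-one-out Q² and S_LOO with per-fold refits (re-centering only)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 3:
        raise ValueError("LOO needs at least 3 training rows")
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        m = fit_pls(X[keep], y[keep], min(nc, len(y) - 2))
        press += float((m.predict(X[i:i + 1])[0] - y[i]) ** 2)
    sstot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / sstot, float(np.sqrt(press / n))


def external_stats(model: PLSModel, X_test: np.ndarray, y_test: np.ndarray
                   ) -> tuple[float, float]:
    """(Rtest², S_test) on an external set."""
    y_test = np.asarray(y_test, dtype=float).ravel()
    if len(y_test) < 2:
        raise ValueError("external statistics need at least 2 test rows")
    if np.ptp(y_test) == 0:
        raise ValueError("constant observed vector: correlation undefined")
    pred = model.predict(X_test)
    s = float(np.sqrt(np.mean((pred - y_test) ** 2)))
    if np.ptp(pred) == 0:  # degenerate model: no predictive correlation
        return 0.0, s
    r = float(np.corrcoef(pred, y_test)[0, 1])
    return r * r, s


def field_contributions(model: PLSModel, block_labels: np.ndarray) -> dict[str, float]:
    """Fraction of the explained y-variance attributable to each field block.

    Component a explains q_a²·(t_a't_a) of the response sum of squares; that
    share is split over blocks by the squared x-weights (unit-norm per
    component), then normalized to sum to 1.
    """
    block_labels = np.asarray(block_labels)
    blocks = []
    for b in block_labels:
        if b not in blocks:
            blocks.append(b)
    if len(blocks) == 1:
        return {blocks[0]: 1.0}
    expl = model.y_loadings ** 2 * model.score_ssq  # per component
    contrib = {b: 0.0 for b in blocks}
    for a in range(model.n_components):
        w2 = model.x_weights[:, a] ** 2
        for b in blocks:
            contrib[b] += float(expl[a] * w2[block_labels == b].sum())
    total = sum(contrib.values())
    if total <= 0:
        return {b: 1.0 / len(blocks) for b in blocks}
    return {b: v / total for b, v in contrib.items()}


# ---------------------------------------------------------------------------
# model selection on a FieldMatrix


@dataclass
class ModelReport:
    fields: tuple[str, ...]
    n_components: int
    r2: float
    s: float
    q2: float
    s_loo: float
    rtest2: float | None
    s_test: float | None
    contributions: dict[str, float]
    predictions: pd.DataFrame  # id, experimental_pKi, predicted_pKi, split
    model: PLSModel
    matrix: FieldMatrix

    @property
    def label(self) -> str:
        return "".join("S" if f == "steric" else "E" for f in self.fields)

    def summary_row(self) -> dict:
        row = {"fields": self.label, "NC": self.n_components,
               "R2": round(self.r2, 2), "S": round(self.s, 2),
               "Q2": round(self.q2, 2), "S_LOO": round(self.s_loo, 2)}
        if self.rtest2 is not None:
            row["Rtest2"] = round(self.rtest2, 2)
            row["S_test"] = round(self.s_test, 2)
        for b in ("steric", "electrostatic"):
            key = "%S" if b == "steric" else "%E"
            row[key] = round(self.contributions.get(b, 0.0), 2)
        return row


def _rows_for(fm: FieldMatrix, ids: list[str]) -> np.ndarray:
    index = {cid: k for k, cid in enumerate(fm.compound_ids)}
    missing = [i for i in ids if i not in index]
    if missing:
        raise KeyError(f"compounds absent from field matrix: {missing[:5]}")
    return np.array([index[i] for i in ids], dtype=int)


def evaluate_candidate(fm: FieldMatrix, table: ActivityTable,
                       fields_: tuple[str, ...], nc: int) -> ModelReport:
    """Fit one (field set, NC) candidate and compute its full statistics."""
    sub = fm.restrict(list(fields_))
    train = table.subset("train")
    if train.empty:
        train = table.frame  # unlabeled table: everything trains
    train_ids = [str(i) for i in train["id"]]
    rows = _rows_for(sub, train_ids)
    X = sub.modeling_matrix()[rows]
    y = train["pKi"].to_numpy(dtype=float)
    model = fit_pls(X, y, nc, training_ids=train_ids)
    r2, s = training_r2_s(y, model.fitted, nc)
    q2, s_loo = loo_q2(X, y, nc)

    test = table.subset("test")
    rtest2 = s_test = None
    frames = [pd.DataFrame({"id": train_ids, "experimental_pKi": y,
                            "predicted_pKi": model.fitted, "split": "train"})]
    if len(test) >= 2:
        test_ids = [str(i) for i in test["id"]]
        Xt = sub.modeling_matrix()[_rows_for(sub, test_ids)]
        yt = test["pKi"].to_numpy(dtype=float)
        rtest2, s_test = external_stats(model, Xt, yt)
        frames.append(pd.DataFrame({"id": test_ids, "experimental_pKi": yt,
                                    "predicted_pKi": model.predict(Xt),
                                    "split": "test"}))
    preds = pd.concat(frames, ignore_index=True)
    contrib = field_contributions(model, sub.block[sub.alive])
    return ModelReport(fields_, model.n_components, r2, s, q2, s_loo,
                       rtest2, s_test, contrib, preds, model, sub)


def select_model(fm: FieldMatrix, table: ActivityTable,
                 nc_range: range = range(1, 9),
                 field_sets: tuple[tuple[str, ...], ...] = DEFAULT_FIELD_SETS,
                 ) -> ModelReport:
    """Scan candidates and return the highest-Q² model (ties → smaller NC,
    then fewer fields)."""
    best: ModelReport | None = None
    errors: list[str] = []
    for fields_ in field_sets:
        if not set(fields_) <= set(fm.blocks):
            continue
        for nc in nc_range:
            try:
                rep = evaluate_candidate(fm, table, fields_, nc)
            except ValueError as exc:
                errors.append(f"{fields_} nc={nc}: {exc}")
                continue
            if rep.n_components != nc:
                continue  # component extraction stopped early; duplicate of smaller nc
            if best is None or (rep.q2, -rep.n_components, -len(rep.fields)) > \
                    (best.q2, -best.n_components, -len(best.fields)):
                best = rep
    if best is None:
        raise ValueError("no candidate model could be fitted: " + "; ".join(errors[:3]))
    return best


# ---------------------------------------------------------------------------
# contour maps


def contour_maps(report: ModelReport) -> dict[str, np.ndarray]:
    """Per-field coefficient maps (coefficient × column SD) over all grid
    nodes; dead variables contribute 0."""
    fm = report.matrix
    coef_full = np.zeros(fm.X.shape[1])
    coef_full[fm.alive] = report.model.coef
    sd = fm.X.std(axis=0, ddof=1)
    values = coef_full * sd
    out = {}
    for b in report.fields:
        mask = fm.block == b
        out[b] = values[mask][np.argsort(fm.node[mask])]
    return out


def export_contours(report: ModelReport, out_dir: str | Path,
                    percentile: float = 85.0) -> dict[str, dict]:
    """Write one OpenDX map per field; returns iso-levels at ±the given
    percentile of the nonzero absolute map values."""
    if report.matrix.grid is None:
        raise ValueError("field matrix lacks grid metadata")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    maps = contour_maps(report)
    info = {}
    for b, values in maps.items():
        path = out_dir / f"coefficients_{b}.dx"
        write_dx(path, report.matrix.grid, values, name=f"{b}_coeff_sd")
        nz = np.abs(values[values != 0])
        level = float(np.percentile(nz, percentile)) if nz.size else 0.0
        info[b] = {"path": str(path), "iso_positive": level, "iso_negative": -level}
    return info
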