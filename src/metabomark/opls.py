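"""Two-class OPLS-DA with VIP scores, implemented from first principles.

Orthogonal projections to latent structures splits the predictor
variation into a part correlated with the class contrast and parts
orthogonal to it.  For a single response the loop is closed-form (the
NIPALS fixed point for one y is reached in a single step):

    w   = X'y / ||X'y||             predictive weight candidate
    t   = X w                        score
    p   = X't / (t't)                loading
    w_o = p - (w'p) w                orthogonal weight (then normalised)
    t_o = X w_o                      orthogonal score
    p_o = X't_o / (t_o't_o)          orthogonal loading
    X  <- X - t_o p_o'               deflation, repeated n_orth times

after which the predictive component(s) are ordinary PLS1 components of
the deflated matrix, and y_hat = y_mean + sum_a c_a t_a with
c_a = y't_a / (t_a't_a).

Class coding is RRMS -> -1, SPMS -> +1; the decision threshold is 0 and
an exact tie is assigned RRMS (deterministic, with a warning).  VIP for
one predictive component is sqrt(p_bins) * |w_j| / ||w||; with several
predictive components the standard formula weighted by the explained
sum of squares of y is used.  mean(VIP^2) over bins is identically 1.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

CLASS_CODING = {"RRMS": -1.0, "SPMS": 1.0}
SCALINGS = ("uv", "pareto", "center")


@dataclass
class OplsModel:
    """Fitted OPLS-DA state (scaling, orthogonal filter, predictive part)."""

    center: np.ndarray
    scale: np.ndarray
    scaling: str
    n_orth: int
    W_orth: np.ndarray            # bins x n_orth
    P_orth: np.ndarray
    T_orth: np.ndarray            # n x n_orth (training scores)
    W_pred: np.ndarray            # bins x n_pred
    P_pred: np.ndarray
    T_pred: np.ndarray            # n x n_pred
    c: np.ndarray                 # n_pred
    y_mean: float
    class_coding: dict = field(default_factory=lambda: dict(CLASS_CODING))
    bin_labels: list = None
    vip_: np.ndarray = None

    @property
    def w_pred(self) -> np.ndarray:
        """First predictive weight vector (unit norm)."""
        return self.W_pred[:, 0]

    @property
    def t_pred(self) -> np.ndarray:
        return self.T_pred[:, 0]

    @property
    def coef_(self) -> np.ndarray:
        """Effective regression coefficients on the scaled input scale.

        y_hat = y_mean + x_scaled @ coef_.  Note the raw weight w_pred
        (proportional to X'y) is invariant under orthogonal deflation;
        it is this filtered coefficient vector that realigns with the
        class contrast once orthogonal variation is removed.
        """
        p = self.center.size
        B = np.eye(p)
        for a in range(self.n_orth):
            B = B @ (np.eye(p)
                     - np.outer(self.W_orth[:, a], self.P_orth[:, a]))
        beta = np.zeros(p)
        for a in range(self.c.size):
            beta += self.c[a] * (B @ self.W_pred[:, a])
            B = B @ (np.eye(p)
                     - np.outer(self.W_pred[:, a], self.P_pred[:, a]))
        return beta

    # -- persistence -----------------------------------------------------

    def to_json(self, path=None):
        payload = {
            "center": self.center.tolist(), "scale": self.scale.tolist(),
            "scaling": self.scaling, "n_orth": self.n_orth,
            "W_orth": self.W_orth.tolist(), "P_orth": self.P_orth.tolist(),
            "T_orth": self.T_orth.tolist(), "W_pred": self.W_pred.tolist(),
            "P_pred": self.P_pred.tolist(), "T_pred": self.T_pred.tolist(),
            "c": self.c.tolist(), "y_mean": self.y_mean,
            "class_coding": self.class_coding,
            "bin_labels": self.bin_labels,
            "vip": self.vip_.tolist() if self.vip_ is not None else None,
        }
        if path is None:
            return json.dumps(payload)
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, source):
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        arr = lambda key: np.asarray(payload[key], dtype=float)
        return cls(center=arr("center"), scale=arr("scale"),
                   scaling=payload["scaling"], n_orth=payload["n_orth"],
                   W_orth=arr("W_orth"), P_orth=arr("P_orth"),
                   T_orth=arr("T_orth"), W_pred=arr("W_pred"),
                   P_pred=arr("P_pred"), T_pred=arr("T_pred"),
                   c=arr("c"), y_mean=float(payload["y_mean"]),
                   class_coding=payload["class_coding"],
                   bin_labels=payload["bin_labels"],
                   vip_=None if payload["vip"] is None else arr("vip"))


@dataclass
class Prediction:
    score: np.ndarray       # predictive score(s) of each new sample
    y_hat: np.ndarray       # continuous prediction on the +/-1 scale
    label: np.ndarray       # "RRMS" / "SPMS"


def code_classes(labels, coding=None) -> np.ndarray:
    coding = coding or CLASS_CODING
    labels = np.asarray(labels)
    unknown = set(labels) - set(coding)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    return np.array([coding[l] for l in labels], dtype=float)


def _scale_factors(X: np.ndarray, scaling: str) -> np.ndarray:
    if scaling not in SCALINGS:
        raise ValueError(f"scaling must be one of {SCALINGS}")
    if scaling == "center":
        return np.ones(X.shape[1])
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = np.flatnonzero(sd == 0)
        raise ValueError(f"constant bins cannot be scaled: columns "
                         f"{bad.tolist()}")
    return sd if scaling == "uv" else np.sqrt(sd)


def fit_opls_da(X, y_labels, n_orth: int = 1, scaling: str = "uv",
                n_pred: int = 1, bin_labels=None) -> OplsModel:
    """Fit a two-class OPLS-DA model.

    Parameters
    ----------
    X : (n_samples, n_bins) matrix
    y_labels : class labels, both "RRMS" and "SPMS" must occur
    n_orth : orthogonal components removed before the predictive fit
    scaling : "uv" (unit variance), "pareto" or "center"
    n_pred : predictive PLS1 components (1 is the conventional choice
        for a binary contrast)
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X must be 2-D with at least 2 bins")
    y = code_classes(y_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in y")
    if len(y) != X.shape[0]:
        raise ValueError("X and y length mismatch")
    if n_orth < 0 or n_pred < 1:
        raise ValueError("n_orth must be >= 0 and n_pred >= 1")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_orth + n_pred > max_rank:
        raise ValueError(f"n_orth + n_pred = {n_orth + n_pred} exceeds the "
                         f"usable rank {max_rank} of X")

    center = X.mean(axis=0)
    Xc = X - center
    scale = _scale_factors(X, scaling)
    E = Xc / scale
    y_mean = float(y.mean())
    yc = y - y_mean

    n_bins = X.shape[1]
    W_o = np.zeros((n_bins, n_orth))
    P_o = np.zeros((n_bins, n_orth))
    T_o = np.zeros((X.shape[0], n_orth))
    for a in range(n_orth):
        w = E.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("y is uncorrelated with every bin; cannot fit")
        w /= nw
        t = E @ w
        p = E.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            raise ValueError(
                f"no orthogonal variation left for component {a + 1}; "
                "reduce n_orth")
        w_o /= n_wo
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        W_o[:, a], P_o[:, a], T_o[:, a] = w_o, p_o, t_o

    W_p = np.zeros((n_bins, n_pred))
    P_p = np.zeros((n_bins, n_pred))
    T_p = np.zeros((X.shape[0], n_pred))
    c = np.zeros(n_pred)
    for a in range(n_pred):
        w = E.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("no predictive variation left; reduce n_pred")
        w /= nw
        t = E @ w
        p = E.T @ t / (t @ t)
        c[a] = yc @ t / (t @ t)
        E = E - np.outer(t, p)
        W_p[:, a], P_p[:, a], T_p[:, a] = w, p, t

    model = OplsModel(center=center, scale=scale, scaling=scaling,
                      n_orth=n_orth, W_orth=W_o, P_orth=P_o, T_orth=T_o,
                      W_pred=W_p, P_pred=P_p, T_pred=T_p, c=c,
                      y_mean=y_mean,
                      bin_labels=list(bin_labels) if bin_labels is not None
                      else None)
    model.vip_ = vip(model)
    return model


def predict(model: OplsModel, X_new, bin_labels=None) -> Prediction:
    """Classify new samples with a fitted model.

    Training centring/scaling parameters are applied as-is (never
    re-estimated); orthogonal components are filtered out sequentially
    before the predictive projection.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.center.size:
        raise ValueError(
            f"bin mismatch: model expects {model.center.size} bins, got "
            f"{X_new.shape[1]}")
    if bin_labels is not None and model.bin_labels is not None \
            and list(bin_labels) != list(model.bin_labels):
        missing = sorted(set(model.bin_labels) - set(bin_labels))
        extra = sorted(set(bin_labels) - set(model.bin_labels))
        raise ValueError(f"bin mismatch: missing {missing}, extra {extra}")
    E = (X_new - model.center) / model.scale
    for a in range(model.n_orth):
        t_o = E @ model.W_orth[:, a]
        E = E - np.outer(t_o, model.P_orth[:, a])
    scores = np.zeros((X_new.shape[0], model.c.size))
    y_hat = np.full(X_new.shape[0], model.y_mean)
    for a in range(model.c.size):
        t = E @ model.W_pred[:, a]
        scores[:, a] = t
        y_hat = y_hat + model.c[a] * t
        E = E - np.outer(t, model.P_pred[:, a])
    inv = {v: k for k, v in model.class_coding.items()}
    pos, neg = inv[1.0], inv[-1.0]
    if np.any(y_hat == 0):
        warnings.warn("exact decision-boundary tie; assigning RRMS",
                      stacklevel=2)
    label = np.where(y_hat > 0, pos, neg)
    return Prediction(score=scores, y_hat=y_hat, label=label)


def vip(model: OplsModel) -> np.ndarray:
    """Variable importance in projection over the predictive component(s).

    VIP_j = sqrt( p * sum_a SS_a (w_aj / ||w_a||)^2 / sum_a SS_a ) with
    SS_a = c_a^2 t_a't_a the y-sum-of-squares explained by component a.
    With one component this is sqrt(p) |w_j| / ||w|| and mean(VIP^2) = 1.
    """
    p = model.W_pred.shape[0]
    ss = model.c ** 2 * np.einsum("ia,ia->a", model.T_pred, model.T_pred)
    wn = model.W_pred / np.linalg.norm(model.W_pred, axis=0, keepdims=True)
    return np.sqrt(p * (wn ** 2 @ ss) / ss.sum())
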