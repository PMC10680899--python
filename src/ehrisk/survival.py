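"""Baseline-covariate discrete-time survival network (DeepHit-style).

A feed-forward comparator that sees only information available at the index
date.  The network maps a fixed-length baseline feature vector to a
probability mass function over K yearly bins covering the risk horizon plus
one open tail bin ("event after the grid, or never during follow-up"), and
is trained on the censoring-aware first-hitting-time log-likelihood

    L = - sum_events   log P(bin of event)
        - sum_censored log P(T > censoring bin).

The single-event formulation treats death as censoring.  The horizon-risk
transform is the cumulative mass over bins inside the horizon, which makes
the model's output directly comparable (via AUC) with a classifier's score.

Binning convention: an event or censoring at t years from index falls in
bin floor(t) (clipped to the tail); a patient censored in bin j contributes
the probability of surviving past bin j, i.e. mass in bins j+1..K.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import _nn
from .records import PatientRecord

RELU_LEAK = 0.0


@dataclass
class DiscreteTimeGrid:
    """K yearly bins on [0, horizon) plus an open tail bin."""

    horizon_years: int = 10
    n_bins: Optional[int] = None  # defaults to horizon_years

    def __post_init__(self) -> None:
        if self.n_bins is None:
            self.n_bins = self.horizon_years
        if self.n_bins < self.horizon_years:
            raise ValueError("n_bins must be >= horizon_years")

    @property
    def n_outputs(self) -> int:
        return self.n_bins + 1  # + tail bin

    def bin_of(self, t_years: float) -> int:
        if t_years < 0:
            raise ValueError("negative time")
        return min(int(t_years), self.n_bins)


@dataclass
class BaselineFeatureSpec:
    """Which baseline covariates to assemble at the index date."""

    code_indicators: list[str] = field(default_factory=list)
    include_age: bool = True
    include_sex: bool = True
    include_index_lab: bool = True
    index_lab_code: str = "LAB_ALT"

    @property
    def names(self) -> list[str]:
        out = []
        if self.include_age:
            out.append("age_at_index")
        if self.include_sex:
            out.append("sex_male")
        if self.include_index_lab:
            out.append("index_lab_value")
        out.extend(f"has_{c}" for c in self.code_indicators)
        return out


def featurize_baseline(
    record: PatientRecord, index_date: dt.date, spec: BaselineFeatureSpec
) -> np.ndarray:
    """Assemble the baseline vector using only events dated <= index_date.

    The index-lab value is the measurement at the index date (the latest
    at-or-before-index value); if absent it is imputed as 0 — callers
    standardize features before training so the imputation is the mean.
    """
    feats = []
    if spec.include_age:
        feats.append(float(record.age_at(index_date)))
    if spec.include_sex:
        feats.append(1.0 if record.sex == "male" else 0.0)
    if spec.include_index_lab:
        vals = [v for d, v in record.lab_events(spec.index_lab_code) if d <= index_date]
        feats.append(vals[-1] if vals else 0.0)
    for code in spec.code_indicators:
        feats.append(
            1.0 if record.has_code([code], code_type="DX", before=index_date) else 0.0
        )
    return np.array(feats)


class DiscreteTimeSurvivalNet:
    """Two-hidden-layer network outputting a pmf over time bins."""

    def __init__(
        self,
        n_features: int,
        grid: DiscreteTimeGrid,
        hidden: int = 64,
        learning_rate: float = 1e-3,
        epochs: int = 60,
        batch_size: int = 128,
        seed: int = 0,
    ):
        self.grid = grid
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.seed = seed
        rng = np.random.default_rng(seed)
        K = grid.n_outputs
        self.params = {
            "W1": _nn.glorot(rng, (n_features, hidden)),
            "b1": np.zeros(hidden),
            "W2": _nn.glorot(rng, (hidden, hidden)),
            "b2": np.zeros(hidden),
            "W3": _nn.glorot(rng, (hidden, K)),
            "b3": np.zeros(K),
        }
        self._mu = np.zeros(n_features)
        self._sd = np.ones(n_features)
        self.training_log: list[dict] = []

    # -- forward -------------------------------------------------------------

    def _forward(self, X: np.ndarray):
        p = self.params
        a1 = X @ p["W1"] + p["b1"]
        h1 = np.maximum(a1, RELU_LEAK * a1)
        a2 = h1 @ p["W2"] + p["b2"]
        h2 = np.maximum(a2, RELU_LEAK * a2)
        logits = h2 @ p["W3"] + p["b3"]
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        pmf = e / e.sum(axis=1, keepdims=True)
        return pmf, (X, a1, h1, a2, h2)

    def predict_pmf(self, X: np.ndarray) -> np.ndarray:
        """Per-patient pmf over the K+1 bins (rows sum to 1)."""
        Xs = (np.atleast_2d(X) - self._mu) / self._sd
        pmf, _ = self._forward(Xs)
        return pmf

    # -- likelihood ----------------------------------------------------------

    def _loss_and_grads(self, X, bins, events):
        """First-hitting-time negative log-likelihood and its gradients.

        For event patients the target mass is the event's bin; censored
        patients contribute log of the survival mass strictly beyond their
        censoring bin.  d(-logL)/dlogits has the standard softmax form
        pmf - target, where target is the (renormalized) mass restriction.
        """
        pmf, cache = self._forward(X)
        B, K = pmf.shape
        eps = 1e-12
        target = np.zeros_like(pmf)
        ll = np.empty(B)
        ev = events.astype(bool)
        target[ev, bins[ev]] = 1.0
        ll[ev] = np.log(np.clip(pmf[ev, bins[ev]], eps, None))
        for i in np.nonzero(~ev)[0]:
            # censoring beyond the closed bins still leaves the tail mass
            # ("event after the grid") consistent with the observation
            j = min(bins[i], self.grid.n_bins - 1)
            surv = pmf[i, j + 1 :].sum()
            ll[i] = np.log(max(surv, eps))
            if surv > eps:
                target[i, j + 1 :] = pmf[i, j + 1 :] / surv
        loss = float(-ll.mean())
        dlogits = (pmf - target) / B
        X_in, a1, h1, a2, h2 = cache
        p = self.params
        grads = {}
        grads["W3"] = h2.T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        dh2 = dlogits @ p["W3"].T
        da2 = dh2 * (a2 > 0)
        grads["W2"] = h1.T @ da2
        grads["b2"] = da2.sum(axis=0)
        dh1 = da2 @ p["W2"].T
        da1 = dh1 * (a1 > 0)
        grads["W1"] = X_in.T @ da1
        grads["b1"] = da1.sum(axis=0)
        return loss, grads

    # -- training ------------------------------------------------------------

    def fit(
        self,
        X: np.ndarray,
        time_years: np.ndarray,
        event: np.ndarray,
    ) -> "DiscreteTimeSurvivalNet":
        """Train on (time-to-event-or-censor, event flag) pairs.

        Censored patients are retained in the likelihood; an all-censored
        input is rejected since the event distribution is unidentified.
        """
        event = np.asarray(event, dtype=bool)
        if not event.any():
            raise ValueError("all patients censored; nothing to fit")
        X = np.asarray(X, dtype=float)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd == 0, 1.0, sd)
        Xs = (X - self._mu) / self._sd
        bins = np.array([self.grid.bin_of(t) for t in time_years])
        rng = np.random.default_rng(self.seed + 1)
        opt = _nn.Adam(self.params, lr=self.learning_rate)
        self.training_log = []
        for epoch in range(self.epochs):
            order = rng.permutation(len(Xs))
            total, nb = 0.0, 0
            for s in range(0, len(order), self.batch_size):
                sel = order[s : s + self.batch_size]
                loss, grads = self._loss_and_grads(Xs[sel], bins[sel], event[sel])
                opt.step(grads)
                total += loss
                nb += 1
            self.training_log.append({"epoch": epoch, "train_loss": total / nb})
        return self

    def risk_at_horizon(self, X: np.ndarray, horizon_years: Optional[float] = None) -> np.ndarray:
        """Cumulative event probability within the horizon (per patient)."""
        h = self.grid.horizon_years if horizon_years is None else horizon_years
        if h > self.grid.n_bins:
            raise ValueError(
                f"horizon {h} years exceeds the {self.grid.n_bins}-bin grid"
            )
        pmf = self.predict_pmf(X)
        return risk_from_pmf(pmf, int(h))

    def estimated_hazards(self, X: np.ndarray) -> np.ndarray:
        """Per-bin discrete hazards implied by the predicted pmf."""
        pmf = self.predict_pmf(X)
        surv_before = 1.0 - np.cumsum(pmf, axis=1) + pmf
        return pmf[:, : self.grid.n_bins] / np.clip(
            surv_before[:, : self.grid.n_bins], 1e-12, None
        )


def risk_from_pmf(pmf: np.ndarray, horizon_bins: int) -> np.ndarray:
    """Partial sum of the first ``horizon_bins`` bins of each pmf row."""
    return np.atleast_2d(pmf)[:, :horizon_bins].sum(axis=1)


def survival_training_data(
    records: Sequence[PatientRecord],
    index_dates: dict[str, dt.date],
    entries,
    spec: BaselineFeatureSpec,
    outcome_codes: Sequence[str] = ("DX_EVENT",),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Assemble (X, time, event) for every indexed patient with a usable
    time axis: event patients use time-to-diagnosis, others time-to-censor.

    Unlike the classifier path, censored patients are *not* excluded here
    (the likelihood handles censoring), except events before index.
    """
    from .records import years_between

    by_id = {r.patient_id: r for r in records}
    X, times, events, ids = [], [], [], []
    for entry in entries:
        rec = by_id[entry.patient_id]
        idx = index_dates[entry.patient_id]
        if entry.event_date is not None:
            t = years_between(idx, entry.event_date)
            if t < 0:
                continue
            e = True
        else:
            t = years_between(idx, entry.censor_date)
            e = False
        X.append(featurize_baseline(rec, idx, spec))
        times.append(t)
        events.append(e)
        ids.append(entry.patient_id)
    return np.array(X), np.array(times), np.array(events, dtype=bool), ids
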