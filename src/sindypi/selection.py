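"""Validation-based model selection for candidate implicit models.

Candidates fitted over a lambda grid are scored on held-out data, either by
the implicit fit residual or (the default for rational dynamics) by the
relative error of the predicted derivative; the lowest-error model wins,
with ties broken by sparsity and then candidate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .identification import (CandidateModel, NotReducibleError, RationalODE,
                             to_explicit_ode)
from .library import LibraryMatrix, TimeSeriesData

__all__ = ["SelectionReport", "fit_error", "derivative_error",
           "select_model", "cross_reference"]


def fit_error(model: CandidateModel, test_lib: LibraryMatrix) -> float:
    """Relative implicit-fit residual on held-out data.

    ||theta_j(test) - Theta'(test) xi|| / ||theta_j(test)||; invariant to a
    common rescaling of the data because every column scales together.
    """
    if model.failed:
        raise ValueError(f"model failed: {model.error}")
    j = test_lib.column(model.lhs.label)
    target = test_lib.values[:, j]
    tnorm = np.linalg.norm(target)
    if tnorm == 0.0:
        raise ValueError("zero-norm lhs column on test data")
    cols = [test_lib.column(t.label) for t in model.terms]
    pred = test_lib.values[:, cols] @ model.coefficients
    return float(np.linalg.norm(target - pred) / tnorm)


def derivative_error(odes, test_data: TimeSeriesData, details: bool = False):
    """Relative error of the predicted derivative on held-out data.

    ||Xdot_t - Xdot_model|| / ||Xdot_t|| over all states covered by ``odes``;
    samples where a denominator safeguard trips are excluded and counted.
    """
    if isinstance(odes, RationalODE):
        odes = [odes]
    if test_data.Xdot is None:
        raise ValueError("test data carries no derivatives")
    preds, truths = [], []
    excluded = 0
    total = 0
    for ode in odes:
        pred, valid = ode.evaluate(test_data)
        truth = test_data.channel("d" + ode.state_name)
        excluded += int(np.sum(~valid))
        total += valid.size
        preds.append(pred[valid])
        truths.append(truth[valid])
    pred = np.concatenate(preds)
    truth = np.concatenate(truths)
    if pred.size < 0.5 * total:
        # the denominator safeguard excluded most of the test set: the
        # model has a singularity across the data and cannot be scored
        err = float("inf")
    else:
        denom = np.linalg.norm(truth)
        if denom == 0.0:
            err = float(np.linalg.norm(pred - truth))
        else:
            err = float(np.linalg.norm(pred - truth) / denom)
    if details:
        return err, excluded
    return err


@dataclass
class SelectionReport:
    """Per-candidate, per-lambda validation table with the chosen winner."""

    table: list[dict]
    winner: CandidateModel
    winner_ode: RationalODE | None
    criterion: str
    split: str = "80/20 chronological"
    ties: list[int] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.table)

    @property
    def winner_error(self) -> float:
        idx = min(i for i, row in enumerate(self.table) if row["winner"])
        return self.table[idx]["error"]


def select_model(candidates: list[CandidateModel],
                 test_data: TimeSeriesData | None = None,
                 criterion: str = "derivative",
                 test_lib: LibraryMatrix | None = None,
                 state_name: str | None = None,
                 deriv_name: str | None = None,
                 train_data: TimeSeriesData | None = None,
                 tie_band: float = 3.0) -> SelectionReport:
    """Pick the candidate model with the lowest validation error.

    criterion "derivative" converts each candidate to explicit rational form
    and compares predicted derivatives on ``test_data``; criterion "fit"
    scores the implicit residual on ``test_lib``.

    A correct candidate yields a sparse model *and* an accurate fit, so
    models whose error is within ``tie_band`` times the best are treated
    as tied and resolved by smaller support, then lower total polynomial
    degree of the support, then candidate order.  (On clean data every
    monomial multiple of the true implicit relation fits exactly and
    predicts the same derivative; the tie rule keeps the minimal,
    lowest-degree one.)
    """
    if criterion not in ("fit", "derivative"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rows, odes = [], []
    for i, model in enumerate(candidates):
        if model.failed or model.coefficients is None:
            degree = 0
        else:
            degree = model.lhs.degree + sum(
                t.degree for t, c in zip(model.terms, model.coefficients)
                if c != 0.0)
        row = {"index": i, "lhs": model.lhs.label, "lambda": model.threshold,
               "sparsity": model.sparsity, "degree": degree,
               "residual": model.residual,
               "error": np.inf, "failed": model.failed, "winner": False}
        ode = None
        if not model.failed:
            try:
                if criterion == "fit":
                    row["error"] = fit_error(model, test_lib)
                else:
                    ode = to_explicit_ode(model, state_name or "x1",
                                          deriv_name=deriv_name,
                                          train_data=train_data)
                    row["error"] = derivative_error(ode, test_data)
            except (NotReducibleError, ValueError) as exc:
                row["failed"] = True
                row["note"] = str(exc)
        if not np.isfinite(row["error"]):
            row["failed"] = True
        rows.append(row)
        odes.append(ode)

    viable = [r for r in rows if not r["failed"]]
    if not viable:
        raise ValueError("all candidate models failed")
    best_err = min(r["error"] for r in viable)
    # errors below ~single precision are numerically indistinguishable
    band = max(tie_band * best_err, 1e-6)
    tied = [r for r in viable if r["error"] <= band]
    nonempty = [r for r in tied if r["sparsity"] > 0]
    if nonempty:
        tied = nonempty
    best = min(tied, key=lambda r: (r["sparsity"], r["degree"], r["index"]))
    best["winner"] = True
    ties = [r["index"] for r in tied if r["index"] != best["index"]]
    return SelectionReport(table=rows, winner=candidates[best["index"]],
                           winner_ode=odes[best["index"]],
                           criterion=criterion, ties=ties)


def cross_reference(candidates: list[CandidateModel]) -> list[list[int]]:
    """Group candidates whose implied implicit supports coincide.

    Models fitted with different left-hand sides but describing the same
    implicit relation share a support; agreement across candidates is
    corroborating evidence for the identified structure.  Groups are sorted
    largest-first, ties by first member.
    """
    if len(candidates) < 2:
        raise ValueError("cross-reference needs at least 2 candidates")
    groups: dict[frozenset, list[int]] = {}
    for i, model in enumerate(candidates):
        if model.failed:
            key = frozenset([f"<failed:{i}>"])
        else:
            key = model.implicit_support
        groups.setdefault(key, []).append(i)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))
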