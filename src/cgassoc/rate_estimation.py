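"""Conversion of association probabilities to rate constants and benchmarking.

A simulated association probability ``P_i`` (fraction of trajectories that
formed an encounter complex) is mapped onto an association rate constant by
an affine transform in log space::

    kon_i = kon_min * 10 ** ( (P_i - P_min) / (P_max - P_min) * N )

``P_min`` / ``P_max`` are the extreme probabilities over the analyzed complex
set, ``kon_min`` (default 1.03e5 M^-1 s^-1) is the smallest experimental rate
in the benchmark and ``N`` (default 4) the number of orders of magnitude the
benchmark spans.  There is no free parameter fitted to the experimental
rates.  Probabilities outside ``[P_min, P_max]`` (when a frozen model is
applied to new complexes) are censored as "< kon_min" or "> kon_min * 10^N".

Benchmark-level agreement is summarized by the Pearson correlation between
log10 simulated and log10 experimental rates, and by the count of complexes
whose rates are off by more than one order of magnitude.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .cg_model import CoarseProtein, NativeContactMap
    from .forcefield import HybridForceField
    from .kmc_engine import SimulationConfig, TrajectoryRecord

__all__ = [
    "RateModel",
    "BenchmarkComplex",
    "ErrorSummary",
    "probability_to_rate",
    "censor_label",
    "log_ratio_errors",
    "pearson_correlation",
    "read_manifest",
    "omega_scan",
    "criteria_scan",
    "default_criteria_grids",
]


@dataclass(frozen=True)
class RateModel:
    """Probability-to-rate mapping anchored on a benchmark's extremes."""

    p_min: float
    p_max: float
    kon_min: float = 1.03e5
    n_orders: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_min <= 1.0 and 0.0 <= self.p_max <= 1.0):
            raise ValueError("p_min and p_max must be probabilities")
        if self.p_max <= self.p_min:
            raise ValueError("degenerate ensemble: p_max must exceed p_min")
        if self.kon_min <= 0 or self.n_orders <= 0:
            raise ValueError("kon_min and n_orders must be positive")

    @classmethod
    def from_probabilities(
        cls, probabilities: Sequence[float], kon_min: float = 1.03e5, n_orders: float = 4.0
    ) -> "RateModel":
        p = np.asarray(probabilities, dtype=float)
        return cls(float(p.min()), float(p.max()), kon_min, n_orders)

    @property
    def kon_max(self) -> float:
        return self.kon_min * 10.0**self.n_orders


def probability_to_rate(p: float, model: RateModel) -> float:
    """Association rate constant (M^-1 s^-1) for probability ``p``.

    Strictly increasing in ``p``; log10(kon) is affine in ``p``.  The formula
    extrapolates naturally outside ``[p_min, p_max]``; use
    :func:`censor_label` to report such values as bounds.
    """
    exponent = (p - model.p_min) / (model.p_max - model.p_min) * model.n_orders
    return model.kon_min * 10.0**exponent


def censor_label(p: float, model: RateModel) -> str:
    """Empty string in range, else a censored bound string."""
    if p < model.p_min:
        return f"< {model.kon_min:.3g} M^-1 s^-1"
    if p > model.p_max:
        return f"> {model.kon_max:.3g} M^-1 s^-1"
    return ""


@dataclass(frozen=True)
class ErrorSummary:
    """Per-complex log10(kon_calc / kon_exp) and order-of-magnitude errors."""

    log_ratios: np.ndarray
    n_overestimated: int
    n_underestimated: int
    n_correct: int

    @property
    def n_total(self) -> int:
        return len(self.log_ratios)

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n_total


def log_ratio_errors(
    kon_calc: Sequence[float], kon_exp: Sequence[float]
) -> ErrorSummary:
    """Flag complexes whose simulated rate is off by > 1 order of magnitude."""
    calc = np.asarray(kon_calc, dtype=float)
    exp = np.asarray(kon_exp, dtype=float)
    if calc.shape != exp.shape or calc.ndim != 1:
        raise ValueError("kon_calc and kon_exp must be equal-length 1-D sequences")
    if np.any(calc <= 0) or np.any(exp <= 0):
        raise ValueError("rate constants must be positive")
    ratios = np.log10(calc / exp)
    over = int(np.sum(ratios > 1.0))
    under = int(np.sum(ratios < -1.0))
    return ErrorSummary(ratios, over, under, len(ratios) - over - under)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length series of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input series")
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# benchmark handling
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "complex_id", "structure", "receptor_chains", "ligand_chains",
    "kon_exp", "ionic_strength",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated benchmark manifest.

    Columns: complex_id, structure (PDB path), receptor_chains,
    ligand_chains (e.g. ``AB``), kon_exp (M^-1 s^-1), ionic_strength (M).
    """
    table = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in MANIFEST_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"manifest is missing columns {missing}")
    if (table["kon_exp"] <= 0).any():
        raise ValueError("experimental rates must be positive")
    return table


@dataclass
class BenchmarkComplex:
    """An in-memory benchmark entry ready for simulation."""

    complex_id: str
    receptor: "CoarseProtein"
    ligand: "CoarseProtein"
    contacts: "NativeContactMap"
    kon_exp: float
    ionic_strength: float | None = None


def evaluate_benchmark(
    probabilities: Sequence[float],
    kon_exp: Sequence[float],
    kon_min: float = 1.03e5,
    n_orders: float = 4.0,
) -> tuple[np.ndarray, float, ErrorSummary, RateModel]:
    """Rates, PCC (on log10 rates) and error counts for one probability set."""
    model = RateModel.from_probabilities(probabilities, kon_min, n_orders)
    rates = np.array([probability_to_rate(p, model) for p in probabilities])
    pcc = pearson_correlation(np.log10(rates), np.log10(np.asarray(kon_exp, dtype=float)))
    errors = log_ratio_errors(rates, kon_exp)
    return rates, pcc, errors, model


def omega_scan(
    complexes: Sequence[BenchmarkComplex],
    omegas: Sequence[float],
    ff: "HybridForceField",
    config: "SimulationConfig",
    kon_min: float = 1.03e5,
    n_orders: float = 4.0,
) -> pd.DataFrame:
    """Re-simulate the benchmark per force-field weight and tabulate PCC.

    Metropolis acceptance depends on omega, so each omega is a full
    re-simulation (no energy re-weighting shortcut).  ``p_min``/``p_max``
    are recomputed per omega.  Returns a table with one row per omega:
    omega, per-complex probabilities, PCC and order-of-magnitude error count.
    """
    from .kmc_engine import run_ensemble  # local import to avoid a cycle

    if len(complexes) < 3:
        raise ValueError("need at least 3 complexes for a correlation")
    kon_exp = [c.kon_exp for c in complexes]
    rows = []
    for omega in omegas:
        ff_w = replace(ff, omega=float(omega))
        probs = [
            run_ensemble(c.receptor, c.ligand, ff_w, c.contacts, config).probability
            for c in complexes
        ]
        try:
            _, pcc, errors, _ = evaluate_benchmark(probs, kon_exp, kon_min, n_orders)
            n_err = errors.n_overestimated + errors.n_underestimated
        except ValueError:  # degenerate probability range
            pcc, n_err = np.nan, np.nan
        rows.append({"omega": float(omega), "pcc": pcc, "n_errors": n_err,
                     "probabilities": probs})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# criteria scan
# ---------------------------------------------------------------------------

def default_criteria_grids() -> dict[str, np.ndarray]:
    """The standard scan grids for the encounter-criteria search.

    Native contact count 0..10 step 1; native contact percentage 0..10% step
    1%; RMSD 0..30 A step 3; interface distance 0..10 A step 1; energy 0 to
    -30 kT step 3.
    """
    return {
        "min_native_contacts": np.arange(0, 11, 1),
        "min_contact_fraction": np.arange(0, 11, 1.0),
        "max_rmsd": np.arange(0, 31, 3.0),
        "max_interface_distance": np.arange(0, 11, 1.0),
        "max_energy": np.arange(0, -31, -3.0),
    }


_GRID_KEYS = ("min_native_contacts", "min_contact_fraction", "max_rmsd",
              "max_interface_distance", "max_energy")


def _combo_probability(stacked: dict[str, np.ndarray], combo: dict[str, float]) -> float:
    """Fraction of trajectories satisfying all thresholds at some step."""
    ok = np.ones_like(stacked["native_contacts"], dtype=bool)
    if combo.get("min_native_contacts") is not None:
        ok &= stacked["native_contacts"] >= combo["min_native_contacts"]
    if combo.get("min_contact_fraction") is not None:
        ok &= stacked["contact_fraction"] >= combo["min_contact_fraction"]
    if combo.get("max_rmsd") is not None:
        ok &= stacked["rmsd"] <= combo["max_rmsd"]
    if combo.get("max_interface_distance") is not None:
        ok &= stacked["interface_distance"] <= combo["max_interface_distance"]
    if combo.get("max_energy") is not None:
        ok &= stacked["energy"] <= combo["max_energy"]
    return float(ok.any(axis=1).mean())


def _stack_diagnostics(records: Sequence["TrajectoryRecord"]) -> dict[str, np.ndarray]:
    for r in records:
        if r.diagnostics is None:
            raise ValueError(
                "criteria_scan requires records run with record_diagnostics=True "
                "and terminate_on_association=False"
            )
    return {
        key: np.vstack([r.diagnostics[key] for r in records])
        for key in ("native_contacts", "contact_fraction", "rmsd",
                    "interface_distance", "energy")
    }


def criteria_scan(
    records_per_complex: Mapping[str, Sequence["TrajectoryRecord"]],
    kon_exp: Mapping[str, float],
    grids: Mapping[str, Sequence[float]] | None = None,
    kon_min: float = 1.03e5,
    n_orders: float = 4.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Post-hoc scan of encounter-criteria combinations.

    ``records_per_complex`` must come from ensembles run with termination
    disabled and per-step diagnostics recorded, so every criterion can be
    re-evaluated on the stored trajectories.  For each combination of grid
    values, association probabilities and the benchmark PCC are recomputed;
    the best row (highest PCC) is returned alongside the full table.
    """
    grids = dict(grids or default_criteria_grids())
    ids = list(records_per_complex)
    if len(ids) < 3:
        raise ValueError("need at least 3 complexes for a correlation")
    stacked = {cid: _stack_diagnostics(records_per_complex[cid]) for cid in ids}
    log_exp = np.log10([kon_exp[cid] for cid in ids])

    keys = [k for k in _GRID_KEYS if k in grids]
    rows = []
    for values in itertools.product(*(grids[k] for k in keys)):
        combo = dict(zip(keys, values))
        probs = np.array([_combo_probability(stacked[cid], combo) for cid in ids])
        row = {k: (v if v is None else float(v)) for k, v in combo.items()}
        row["probabilities"] = probs
        if probs.max() > probs.min():
            model = RateModel(probs.min(), probs.max(), kon_min, n_orders)
            log_rates = np.log10([probability_to_rate(p, model) for p in probs])
            row["pcc"] = (
                float(np.corrcoef(log_rates, log_exp)[0, 1]) if np.ptp(log_exp) > 0 else np.nan
            )
        else:
            row["pcc"] = np.nan
        rows.append(row)
    table = pd.DataFrame(rows)
    if table["pcc"].notna().any():
        best = table.loc[table["pcc"].idxmax()]
    else:
        best = table.iloc[0]
    return table, best
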