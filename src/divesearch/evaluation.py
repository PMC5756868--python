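"""Search-chain validation of behavioral annotations against dive events.

A search chain is a maximal run of consecutive search-labeled fixes within
one trip (runs are broken by other labels, invalid fixes, and trip or
segment boundaries). Against the matched dive record, each method gets:

- true-positive rate: % of matched dives whose fix is search-labeled
- false-negative rate: 100 - tp_rate (dives outside search)
- false-positive rate: % of search chains containing no dive
- % relocations searching, mean chain length
- Kendall's tau-b between chain length and dives per chain

``compare_methods`` assembles the full cross-method report for one or more
colonies, adding a kernel-density row (spatially corrected correlation
instead of chain rates) and a machine-learning row (kappa / confusion
matrix) which are assessed with their own metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import dive_ml as ml
from .base import valid_mask
from .density import dutilleul_correlation, kernel_density

log = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "method",
    "colony",
    "n_relocations",
    "n_dives",
    "tp_rate",
    "fp_rate",
    "fn_rate",
    "pct_searching",
    "mean_chain_len",
    "tau",
    "tau_z",
    "tau_p",
]


@dataclass
class SearchChain:
    bird_id: str
    trip_id: str
    start_idx: int  # positional index into the trajectory frame, inclusive
    end_idx: int
    length: int
    n_dives: int


def extract_chains(
    states: np.ndarray, traj: pd.DataFrame, matched_dives: pd.DataFrame
) -> list[SearchChain]:
    """Maximal runs of consecutive search fixes, with their dive counts."""
    if len(states) != len(traj):
        raise ValueError("annotation and trajectory lengths differ")
    dive_count = np.zeros(len(traj), dtype=int)
    if len(matched_dives):
        fi = matched_dives.loc[matched_dives["matched"], "fix_index"].to_numpy(int)
        np.add.at(dive_count, fi, 1)

    trip_col = "trip_id" if "trip_id" in traj.columns else "bird_id"
    trips = traj[trip_col].to_numpy(object)
    birds = traj["bird_id"].to_numpy(object)

    chains: list[SearchChain] = []
    start = None
    for i in range(len(traj) + 1):
        boundary = (
            i == len(traj)
            or states[i] != "search"
            or (i > 0 and trips[i] != trips[i - 1] and start is not None)
        )
        if start is not None and boundary:
            end = i - 1
            chains.append(
                SearchChain(
                    bird_id=str(birds[start]),
                    trip_id=str(trips[start]),
                    start_idx=start,
                    end_idx=end,
                    length=end - start + 1,
                    n_dives=int(dive_count[start : end + 1].sum()),
                )
            )
            start = None
        if i < len(traj) and states[i] == "search" and start is None:
            start = i
    return chains


def kendall_tau(x, y) -> tuple[float, float, float]:
    """Kendall's tau-b with tie correction, normal z and two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    res = stats.kendalltau(x, y)
    tau, p = float(res.statistic), float(res.pvalue)
    if np.isnan(tau):
        return np.nan, np.nan, np.nan
    z = float(np.sign(tau) * stats.norm.isf(max(p, 1e-300) / 2)) if p < 1 else 0.0
    return tau, z, p


@dataclass
class EvalSummary:
    method: str
    colony: str
    n_relocations: int
    n_dives: int
    tp_rate: float
    fp_rate: float
    fn_rate: float
    pct_searching: float
    mean_chain_len: float
    tau: float
    tau_z: float
    tau_p: float
    extras: dict = field(default_factory=dict)


def summarize(
    states: np.ndarray,
    chains: list[SearchChain],
    matched_dives: pd.DataFrame,
    traj: pd.DataFrame,
    method: str = "",
    colony: str = "",
) -> EvalSummary:
    """Table-style rates for one annotation method."""
    ok = valid_mask(traj)
    n_valid = int(ok.sum())
    matched = matched_dives[matched_dives["matched"]] if len(matched_dives) else matched_dives
    n_dives = len(matched)

    search_fix = np.asarray(states) == "search"
    if n_dives:
        on_search = search_fix[matched["fix_index"].to_numpy(int)]
        tp = 100.0 * on_search.sum() / n_dives
        fn = 100.0 - tp
    else:
        log.warning("%s/%s: no matched dives; dive rates undefined", method, colony)
        tp = fn = np.nan

    fp = 100.0 * sum(c.n_dives == 0 for c in chains) / len(chains) if chains else np.nan
    pct_search = 100.0 * int(search_fix[ok].sum()) / n_valid if n_valid else np.nan
    mean_len = float(np.mean([c.length for c in chains])) if chains else np.nan

    if len(chains) >= 2:
        tau, z, p = kendall_tau([c.length for c in chains], [c.n_dives for c in chains])
    else:
        tau = z = p = np.nan

    return EvalSummary(
        method=method,
        colony=colony,
        n_relocations=n_valid,
        n_dives=n_dives,
        tp_rate=tp,
        fp_rate=fp,
        fn_rate=fn,
        pct_searching=pct_search,
        mean_chain_len=mean_len,
        tau=tau,
        tau_z=z,
        tau_p=p,
    )


def evaluate_annotation(
    states, traj, matched_dives, method: str = "", colony: str = ""
) -> EvalSummary:
    chains = extract_chains(np.asarray(states, dtype=object), traj, matched_dives)
    return summarize(np.asarray(states, dtype=object), chains, matched_dives, traj, method, colony)


def truth_annotation(traj: pd.DataFrame, truth: pd.DataFrame) -> np.ndarray:
    """Latent-state labels aligned to the trajectory (ground-truth method)."""
    key = truth.set_index(["bird_id", truth["t"].round(0)])["true_state"]
    states = np.full(len(traj), "excluded", dtype=object)
    ok = valid_mask(traj)
    idx = pd.MultiIndex.from_arrays([traj["bird_id"], traj["t"].round(0)])
    mapped = key.reindex(idx).to_numpy(object)
    fill = ok & pd.notna(mapped)
    states[fill] = mapped[fill]
    return states


def compare_methods(
    datasets: dict,
    annotators: dict,
    ml_params: dict | None = None,
    density_bandwidth: float = 10000.0,
    density_cell: float = 10000.0,
) -> pd.DataFrame:
    """Cross-method, cross-colony comparison report.

    ``datasets`` maps colony name -> dict with keys ``traj`` (processed
    trajectory), ``dives`` (matched dives) and optionally ``truth``.
    ``annotators`` maps method name -> TrajectoryAnnotator instance (cloned
    per colony by refitting). A method failure is recorded in its row's
    ``error`` column and the rest proceed. Colonies are processed
    independently throughout.
    """
    rows = []
    for colony, data in datasets.items():
        traj, dives = data["traj"], data["dives"]
        for name, ann in annotators.items():
            try:
                states = ann.fit_predict(traj)
                s = evaluate_annotation(states, traj, dives, name, colony)
                rows.append({**s.__dict__, "error": ""})
            except Exception as exc:  # failures recorded, others proceed
                log.warning("%s failed on %s: %s", name, colony, exc)
                rows.append({"method": name, "colony": colony, "error": str(exc)})
        if "truth" in data and data["truth"] is not None:
            states = truth_annotation(traj, data["truth"])
            s = evaluate_annotation(states, traj, dives, "truth", colony)
            rows.append({**s.__dict__, "error": ""})

        # kernel density + spatially corrected correlation
        try:
            ok = valid_mask(traj)
            tx = traj["x"].to_numpy(float)[ok]
            ty = traj["y"].to_numpy(float)[ok]
            track_grid = kernel_density(tx, ty, bandwidth=density_bandwidth, cell=density_cell)
            m = dives[dives["matched"]]
            fi = m["fix_index"].to_numpy(int)
            dive_grid = kernel_density(
                traj["x"].to_numpy(float)[fi],
                traj["y"].to_numpy(float)[fi],
                bandwidth=density_bandwidth,
                cell=density_cell,
                extent=(track_grid.x0, track_grid.y0, track_grid.n_rows, track_grid.n_cols),
            )
            dres = dutilleul_correlation(track_grid, dive_grid)
            rows.append(
                {
                    "method": "kernel_density",
                    "colony": colony,
                    "n_relocations": int(ok.sum()),
                    "n_dives": int(dives["matched"].sum()),
                    "dutilleul_r": dres.r,
                    "dutilleul_F": dres.F,
                    "dutilleul_df": dres.df,
                    "dutilleul_p": dres.p,
                    "error": "",
                }
            )
        except Exception as exc:
            rows.append({"method": "kernel_density", "colony": colony, "error": str(exc)})

        # machine learning: dive prediction
        try:
            params = dict(ml_params or {})
            rs = params.pop("random_state", 0)
            tbl = ml.build_feature_table(traj, dives)
            train, test = ml.split_train_test(tbl, random_state=rs)
            clf = ml.DiveClassifier(random_state=rs, **params).fit(train)
            cm, kappa, recall = ml.evaluate_dive_model(clf, test)
            rows.append(
                {
                    "method": "ml_gbm",
                    "colony": colony,
                    "n_relocations": len(tbl),
                    "n_dives": int(tbl["dive"].sum()),
                    "kappa": kappa,
                    "ml_recall_pct": recall,
                    "tp": cm.tp,
                    "fp": cm.fp,
                    "fn": cm.fn,
                    "tn": cm.tn,
                    "error": "",
                }
            )
        except Exception as exc:
            rows.append({"method": "ml_gbm", "colony": colony, "error": str(exc)})

    report = pd.DataFrame(rows)
    extra = [c for c in report.columns if c not in REPORT_COLUMNS and c != "extras"]
    cols = REPORT_COLUMNS + [c for c in extra if c in report.columns]
    for c in cols:
        if c not in report.columns:
            report[c] = np.nan
    return report[cols]


def write_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, index=False, float_format="%.6f")
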