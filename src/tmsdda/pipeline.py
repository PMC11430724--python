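"""End-to-end orchestration: generate -> epoch -> features -> decode -> stats.

The pipeline consumes synthetic sessions (or session files), cuts
stimulus-locked epochs, extracts per-trial DDA features, runs the
SVD-subspace decoder separately per stimulation site and TMS condition,
and feeds the behavioral and decoding accuracies into the statistics
layer (relative accuracy, one-sided Bayes factors, Type-III
regression).  A single seed fans out into named substreams so each stage
is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dda import DDAModelSpec, WindowConfig
from .decoder import CVConfig, DecodingResult, evaluate, relative_decoding_accuracy
from .features import make_triples, trial_feature_matrix
from .io import Montage, default_montage, extract_epochs
from .stats import (
    bf_paired_onesided,
    bf_robustness,
    hit_rates,
    relative_accuracy,
    accuracy_regression,
)
from .synth import Session, SessionConfig, generate_session

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_decoding", "run_stats", "decode_session"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one pipeline run needs; exactly one input source active."""

    session: SessionConfig = field(default_factory=SessionConfig)
    input_dir: str | None = None  # read sessions from files instead of generating
    n_participants: int = 2
    epoch_window: tuple[float, float] = (0.0, 0.5)
    anchor: str = "stim_onset"
    delays: tuple[int, int] = (6, 16)
    window_ms: float = 30.0
    shift_ms: float = 1.0
    cv: CVConfig = field(default_factory=CVConfig)
    label_col: str = "category"
    out_dir: str | None = None
    seed: int = 0

    @property
    def spec(self) -> DDAModelSpec:
        return DDAModelSpec(delays=self.delays)

    def wincfg(self, sample_rate: float) -> WindowConfig:
        return WindowConfig(self.window_ms, self.shift_ms, sample_rate)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def decode_session(
    session: Session,
    config: PipelineConfig,
    montage: Montage | None = None,
) -> tuple[dict[tuple[str, bool], DecodingResult], pd.DataFrame]:
    """Decode one session per (site, TMS) condition.

    Features are extracted once for all trials and then split by
    condition; each condition is evaluated independently with the
    time-aware balanced CV.  Returns the per-condition results and the
    TMS-minus-sham relative decoding accuracy table.
    """
    montage = montage or default_montage()
    triples = make_triples(montage)
    epochs, n_skipped = extract_epochs(
        session.record, session.events, config.anchor, config.epoch_window
    )
    if n_skipped:
        logger.warning("%s: %d trials skipped at epoching", session.participant, n_skipped)
    wincfg = config.wincfg(session.record.sample_rate)
    tfm = trial_feature_matrix(epochs, triples, config.spec, wincfg)
    results: dict[tuple[str, bool], DecodingResult] = {}
    for site in sorted(set(tfm.meta["site"])):
        for tms in (True, False):
            mask = (tfm.meta["site"] == site) & (tfm.meta["tms"].astype(bool) == tms)
            sub = tfm.subset(np.nonzero(mask.to_numpy())[0])
            if len(sub) == 0:
                continue
            cond_key = sum(ord(c) for c in site) * 2 + int(tms)  # stable across runs
            cv = replace(config.cv, seed=config.cv.seed + cond_key)
            results[(site, tms)] = evaluate(sub, cv, config.label_col)
    rel = relative_decoding_accuracy(results)
    return results, rel


def _load_sessions(input_dir: str) -> list[Session]:
    """Read sessions written by the simulate stage (or matching files).

    Expects ``<pid>_eeg.bin`` (+ sidecar) or ``<pid>_eeg.edf``,
    ``<pid>_events.csv``, and a shared ``behavior.csv``.
    """
    from .io import read_eeg_record, read_event_table

    root = Path(input_dir)
    beh_path = root / "behavior.csv"
    behavior = pd.read_csv(beh_path) if beh_path.exists() else None
    sessions = []
    for ev_path in sorted(root.glob("*_events.csv")):
        pid = ev_path.name[: -len("_events.csv")]
        eeg = root / f"{pid}_eeg.bin"
        if not eeg.exists():
            eeg = root / f"{pid}_eeg.edf"
        record = read_eeg_record(eeg)
        events = read_event_table(ev_path)
        beh = (
            behavior[behavior["participant"] == pid].reset_index(drop=True)
            if behavior is not None
            else pd.DataFrame()
        )
        sessions.append(Session(pid, record, events, beh))
    if not sessions:
        raise FileNotFoundError(f"no '*_events.csv' session files under {root}")
    return sessions


def run_decoding(config: PipelineConfig) -> dict:
    """Run the decoding stage for every participant.

    Generates each session from the config's generator settings — or, when
    ``input_dir`` is set, loads session files instead — decodes it per
    condition, and writes per-condition result JSONs plus a manifest when
    ``out_dir`` is set.  Returns ``{participant: {"results": ...,
    "relative": ..., "behavior": ...}}``.
    """
    t0 = time.time()
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    montage = default_montage()
    if config.input_dir is not None:
        sessions = _load_sessions(config.input_dir)
    else:
        sessions = (
            generate_session(config.session, f"S{i + 1:02d}", seed=config.seed,
                             montage=montage)
            for i in range(config.n_participants)
        )
    all_out: dict[str, dict] = {}
    for session in sessions:
        pid = session.participant
        results, rel = decode_session(session, config, montage)
        all_out[pid] = {"results": results, "relative": rel, "behavior": session.behavior}
        if out:
            for (site, tms), res in results.items():
                cond = f"{site}_{'tms' if tms else 'sham'}"
                res.to_json(out / f"decoding_{pid}_{cond}.json")
            rel.to_csv(out / f"relative_decoding_{pid}.csv", index=False)
        logger.info("decoded %s (%d conditions)", pid, len(results))
    if out:
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "n_participants": config.n_participants,
            "elapsed_s": round(time.time() - t0, 2),
            "numpy": np.__version__,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return all_out


def _congruent_direction(unit_value: str, site_category: Mapping[str, str]) -> tuple[str, str]:
    """(measure-1 site, measure-2 site) so the congruent direction is 'greater'."""
    cat = unit_value if unit_value in site_category.values() else None
    if cat is None:
        from .io import CATEGORY_OF_CONSONANT

        cat = CATEGORY_OF_CONSONANT[unit_value]
    sites = {v: k for k, v in site_category.items()}
    m1 = sites[cat]
    m2 = next(s for s in site_category if s != m1)
    return m1, m2


def bf_table(
    behavior: pd.DataFrame,
    unit: str = "category",
    site_category: Mapping[str, str] | None = None,
    prior_width: float | None = None,
    year: str | int = "synthetic",
) -> pd.DataFrame:
    """Bayesian paired t-test table over relative accuracies.

    For each unit (category or phoneme) the paired difference is the
    relative accuracy under the congruent site's TMS minus under the
    other site's TMS, one participant per pair, tested one-sided in the
    congruent direction (mirroring the Measure 1 > Measure 2 layout of
    standard Bayesian t-test reports).
    """
    from .stats import DEFAULT_PRIOR_WIDTH

    site_category = site_category or {"LipM1": "bilabial", "TongM1": "alveolar"}
    r = prior_width if prior_width is not None else DEFAULT_PRIOR_WIDTH
    rel = relative_accuracy(hit_rates(behavior, unit=unit))
    rows = []
    for unit_value in sorted(set(rel["unit"])):
        m1, m2 = _congruent_direction(unit_value, site_category)
        sub = rel[rel["unit"] == unit_value].pivot_table(
            index="participant", columns="site", values="relative_accuracy"
        )
        if m1 not in sub.columns or m2 not in sub.columns:
            raise ValueError(f"missing site column for unit {unit_value!r}")
        diffs = (sub[m1] - sub[m2]).dropna().to_numpy()
        res = bf_paired_onesided(diffs, r=r)
        rows.append(
            {
                "Year": year,
                "Category": unit_value,
                "Measure 1": f"{m1} TMS",
                "Measure 2": f"{m2} TMS",
                "BF_+0": res.bf_plus0,
                "Error %": res.error_pct,
                "t": res.t_statistic,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)


def run_stats(
    config: PipelineConfig,
    decoding: Mapping[str, dict],
    behavior: pd.DataFrame | None = None,
) -> dict:
    """Statistics stage: accuracy tables, Bayes factors, regression.

    ``decoding`` is the mapping returned by :func:`run_decoding`.  Writes
    report CSVs (Bayes-factor tables, robustness curves, the regression
    table) plus a summary JSON when ``out_dir`` is set, and returns the
    tables in memory.
    """
    if behavior is None:
        behavior = pd.concat(
            [d["behavior"] for d in decoding.values()], ignore_index=True
        )
    site_category = dict(config.session.site_category)
    tables: dict[str, pd.DataFrame] = {}
    tables["bf_category"] = bf_table(behavior, "category", site_category)
    tables["bf_phoneme"] = bf_table(behavior, "phoneme", site_category)

    # robustness of the category-level BFs to the prior width
    rel = relative_accuracy(hit_rates(behavior, unit="category"))
    rob_rows = []
    for unit_value in sorted(set(rel["unit"])):
        m1, m2 = _congruent_direction(unit_value, site_category)
        sub = rel[rel["unit"] == unit_value].pivot_table(
            index="participant", columns="site", values="relative_accuracy"
        )
        diffs = (sub[m1] - sub[m2]).dropna().to_numpy()
        curve = bf_robustness(diffs)
        for r, bf in zip(curve.prior_widths, curve.bf_plus0):
            rob_rows.append({"unit": unit_value, "r": r, "bf_plus0": bf})
    tables["bf_robustness"] = pd.DataFrame(rob_rows)

    # decoding vs task accuracy, one cell per participant x unit x condition
    cells = []
    rates = hit_rates(behavior, unit="category")
    for pid, d in decoding.items():
        for (site, tms), res in d["results"].items():
            for cls, acc in res.per_class_accuracy.items():
                cell = rates[
                    (rates["participant"] == pid)
                    & (rates["site"] == site)
                    & (rates["tms"].astype(bool) == tms)
                    & (rates["unit"] == cls)
                ]
                if len(cell) != 1:
                    continue
                cells.append(
                    {
                        "participant": pid,
                        "target": f"{site}_{'tms' if tms else 'sham'}",
                        "category": cls,
                        "task_accuracy": float(cell["hit_rate"].iloc[0]),
                        "decoding_accuracy": acc,
                    }
                )
    cells_df = pd.DataFrame(cells)
    tables["cells"] = cells_df
    if len(cells_df) >= 12 and cells_df["participant"].nunique() >= 2:
        # the full interaction model needs enough cells per parameter
        tests, re_var = accuracy_regression(
            cells_df, include_interactions=len(cells_df) >= 48
        )
        tables["regression"] = pd.DataFrame(
            [
                {"Effect": t.effect, "df": f"{t.df_num:g}, {t.df_den:g}", "F": t.F, "p": t.p}
                for t in tests
            ]
        )
        tables["regression"].attrs["random_intercept_variance"] = re_var

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, tab in tables.items():
            tab.to_csv(out / f"{name}.csv", index=False)
        summary = {
            "bf_category": tables["bf_category"]["BF_+0"].round(4).tolist(),
            "n_cells": len(cells_df),
        }
        (out / "stats_summary.json").write_text(json.dumps(summary, indent=1))
    return tables
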