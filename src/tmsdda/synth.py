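"""Synthetic TMS-EEG phoneme-discrimination sessions.

Generates complete sessions — a continuous 64-channel EEG record, the
per-trial event table, and behavioral responses — with the study's
design baked in: two stimulation sites (lip and tongue motor cortex),
120 trials per run (80 TMS + 40 control), a 4-consonant x 5-vowel
stimulus inventory in CV/VC order (40 pairs), 500 ms noise-immersed
stimuli and paired TMS pulses 100 and 50 ms before the phoneme onset.

Neural class structure is planted through the same delay model the DDA
engine fits: each phoneme category drives a latent source with its own
coefficients; when the stimulation site matches the category's
articulator the TMS condition shifts those coefficients (``tms_boost``).
The latent source is mixed into electrodes around the left motor cortex
and buried in 1/f background noise.  Behavioral responses are Bernoulli
draws whose hit probability moves up (congruent) or down (incongruent)
under TMS, which plants a relative-accuracy double dissociation of
controllable size.

Everything is a pure function of (config, ids, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CATEGORY_OF_CONSONANT,
    MISSING,
    EventTable,
    EEGRecord,
    Montage,
    default_montage,
    phoneme_pair_inventory,
)

__all__ = [
    "SessionConfig",
    "Session",
    "simulate_latent_source",
    "generate_trial_eeg",
    "generate_session",
    "generate_behavioral_cohort",
    "DivergentSimulation",
]


class DivergentSimulation(RuntimeError):
    """Latent simulation exceeded the stability bound on every retry."""


@dataclass(frozen=True)
class TrialCounts:
    total: int = 120
    tms: int = 80
    control: int = 40


@dataclass(frozen=True)
class SessionConfig:
    """Study-design and forward-model parameters of a synthetic session.

    Class coefficients are per phoneme category; the delay recursion they
    parameterize sits near a damped resonance of the two-delay feedback
    loop so windowed fits carry class information at realistic
    signal-to-noise.  ``tms_boost`` is added to the congruent category's
    coefficients on TMS trials, pushing the two classes further apart and
    thereby raising decodability in the congruent condition.
    """

    n_channels: int = 64
    sample_rate: float = 2000.0
    consonants: tuple[str, ...] = ("b", "p", "d", "t")
    vowels: tuple[str, ...] = ("i", "E", "A", "u", "oU")
    orders: tuple[str, ...] = ("CV", "VC")
    trials_per_run: TrialCounts = TrialCounts()
    sites: tuple[str, ...] = ("LipM1", "TongM1")
    site_category: Mapping[str, str] = field(
        default_factory=lambda: {"LipM1": "bilabial", "TongM1": "alveolar"}
    )
    class_coefficients: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "bilabial": (115.0, -175.0, 6.0),
            "alveolar": (145.0, -195.0, 6.0),
        }
    )
    tms_boost: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "bilabial": (-10.0, 5.0, 0.0),
            "alveolar": (10.0, -5.0, 0.0),
        }
    )
    #: multiplicative excitability gain on the congruent category's signal
    #: under TMS (facilitated psychomotor activity -> higher electrode SNR)
    tms_gain_boost: float = 1.4
    delays: tuple[int, int] = (6, 16)
    behavioral_base_hit: float = 0.75
    behavioral_congruency_delta: float = 0.15
    p_miss: float = 0.02
    noise_sd: float = 0.01  # innovation sd of the latent recursion
    pink_noise_scale: float = 1.0  # uV, per-channel 1/f background
    signal_gain_uv: float = 5.0  # latent-to-electrode gain at the mixing peak
    motor_center: str = "C3"
    motor_sigma_mm: float = 35.0
    tms_artifact_amplitude: float = 0.0  # uV; damped 10 ms cosine per pulse
    stim_duration: float = 0.5
    iti: float = 3.0
    iti_jitter: float = 0.5
    lead_time: float = 5.0  # s of record before the first / after the last trial
    run_gap: float = 10.0  # s between the two stimulation-site runs
    stability_bound: float = 20.0
    max_retries: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        c = self.trials_per_run
        if c.tms + c.control != c.total:
            raise ValueError("trials_per_run: tms + control must equal total")
        for p in (self.behavioral_base_hit, self.p_miss):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.behavioral_congruency_delta <= 1.0:
            raise ValueError("behavioral_congruency_delta must lie in [0, 1]")
        for cat in set(self.site_category.values()):
            if cat not in self.class_coefficients:
                raise ValueError(f"no class coefficients for category {cat!r}")

    @property
    def inventory(self) -> list[str]:
        return phoneme_pair_inventory(self.consonants, self.vowels, self.orders)


@dataclass
class Session:
    """One synthetic participant session: EEG, events and behavior."""

    participant: str
    record: EEGRecord
    events: EventTable
    behavior: pd.DataFrame


# ---------------------------------------------------------------------------
# latent source


def simulate_latent_source(
    coeffs: Sequence[float],
    delays: Sequence[int],
    n_samples: int,
    innovation_sd: float,
    seed: int | np.random.SeedSequence,
    sample_rate: float = 2000.0,
    bound: float = 20.0,
    max_retries: int = 100,
) -> np.ndarray:
    """Simulate the delay recursion the DDA model describes.

    Euler step with ``h = 1/sample_rate``::

        x[t+1] = x[t] + h*(a1*x[t-tau1] + a2*x[t-tau2] + a3*x[t-tau1]**2) + eps[t]

    with standard-normal initial history and Gaussian innovations.  The
    quadratic term can tip near-resonant trajectories into divergence, so
    a stability guard redraws the trajectory from a fresh substream when
    ``|x|`` exceeds ``bound`` (bounded retries).
    """
    a1, a2, a3 = (float(c) for c in coeffs)
    t1, t2 = (int(d) for d in delays)
    m = max(t1, t2)
    if n_samples <= m:
        raise ValueError("n_samples must exceed the maximum delay")
    if innovation_sd < 0:
        raise ValueError("innovation_sd must be non-negative")
    h = 1.0 / sample_rate
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    for child in ss.spawn(max_retries):
        rng = np.random.default_rng(child)
        x = np.empty(n_samples)
        x[: m + 1] = rng.standard_normal(m + 1)
        eps = (
            rng.standard_normal(n_samples) * innovation_sd
            if innovation_sd > 0
            else np.zeros(n_samples)
        )
        ok = True
        for t in range(m, n_samples - 1):
            v = x[t] + h * (a1 * x[t - t1] + a2 * x[t - t2] + a3 * x[t - t1] ** 2) + eps[t + 1]
            if not (-bound < v < bound):
                ok = False
                break
            x[t + 1] = v
        if ok:
            return x
    raise DivergentSimulation(
        f"trajectory diverged on {max_retries} retries for coefficients "
        f"({a1}, {a2}, {a3}); reduce a3 or innovation_sd"
    )


def pink_noise(n_samples: int, rng: np.random.Generator, n_channels: int = 1) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise, shaped in the frequency domain.

    Works on a padded FFT-friendly length (large prime lengths make the
    transform pathologically slow) and in single precision; the result is
    truncated back to ``n_samples``.
    """
    from scipy import fft as sfft

    n_fast = sfft.next_fast_len(n_samples, real=True)
    w = rng.standard_normal((n_channels, n_fast), dtype=np.float32)
    F = sfft.rfft(w, axis=1)
    f = np.fft.rfftfreq(n_fast).astype(np.float32)
    f[0] = f[1] if n_fast > 1 else 1.0
    F /= np.sqrt(f)
    p = sfft.irfft(F, n_fast, axis=1)[:, :n_samples]
    # row-wise std via einsum: float32 axis reductions are slow in numpy
    mu = p.sum(axis=1) / p.shape[1]
    ss = np.einsum("ij,ij->i", p, p) / p.shape[1]
    p /= np.sqrt(ss - mu * mu)[:, None]
    return p


def _mixing_weights(montage: Montage, center: str, sigma_mm: float) -> np.ndarray:
    pos = montage.positions()
    c = montage.positions([center])[0]
    d2 = np.sum((pos - c) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma_mm**2))


def _tms_artifact(n_samples: int, sample_rate: float, amplitude: float) -> np.ndarray:
    """Damped 10 ms cosine transient, as appears after each pulse."""
    n = int(round(0.010 * sample_rate))
    t = np.arange(n) / sample_rate
    return amplitude * np.cos(2 * np.pi * 400.0 * t) * np.exp(-t / 0.002)


def generate_trial_eeg(
    category: str,
    site: str,
    tms: bool,
    cfg: SessionConfig,
    seed: int | np.random.SeedSequence,
    n_samples: int,
    montage: Montage | None = None,
    pulse_offsets_s: tuple[float, ...] = (),
    mixing_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Forward-model one trial: latent class dynamics mixed over channels.

    The latent source uses the category's coefficients, shifted by
    ``tms_boost`` when TMS is on and the stimulated site governs the
    category's articulator.  Instantaneous Gaussian spatial mixing around
    the motor electrode, additive per-channel 1/f noise, and (optionally)
    a damped-cosine TMS artifact at each pulse offset.
    """
    montage = montage or default_montage()
    coeffs = np.asarray(cfg.class_coefficients[category], dtype=float)
    gain = cfg.signal_gain_uv
    if tms and cfg.site_category.get(site) == category:
        coeffs = coeffs + np.asarray(cfg.tms_boost[category], dtype=float)
        gain *= cfg.tms_gain_boost
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_latent, ss_noise = ss.spawn(2)
    latent = simulate_latent_source(
        coeffs,
        cfg.delays,
        n_samples,
        cfg.noise_sd,
        ss_latent,
        cfg.sample_rate,
        cfg.stability_bound,
        cfg.max_retries,
    )
    w = (
        mixing_weights
        if mixing_weights is not None
        else _mixing_weights(montage, cfg.motor_center, cfg.motor_sigma_mm)
    )
    data = np.outer(w, latent) * gain
    if cfg.pink_noise_scale > 0:
        data += cfg.pink_noise_scale * pink_noise(
            n_samples, np.random.default_rng(ss_noise), len(w)
        )
    if tms and cfg.tms_artifact_amplitude > 0 and pulse_offsets_s:
        art = _tms_artifact(n_samples, cfg.sample_rate, cfg.tms_artifact_amplitude)
        for off in pulse_offsets_s:
            i0 = int(round(off * cfg.sample_rate))
            if 0 <= i0 < n_samples:
                k = min(len(art), n_samples - i0)
                data[:, i0 : i0 + k] += art[:k]
    return data


# ---------------------------------------------------------------------------
# schedule and behavior


def _run_schedule(cfg: SessionConfig, site: str, rng: np.random.Generator) -> pd.DataFrame:
    """Pseudo-randomized trial schedule for one run (one site).

    The run is organized in one block per stimulus order; each block
    presents every pair of its order with the block's share of TMS and
    control repetitions, shuffled.
    """
    counts = cfg.trials_per_run
    n_blocks = len(cfg.orders)
    if counts.total % n_blocks or counts.tms % n_blocks or counts.control % n_blocks:
        raise ValueError("trials_per_run must divide evenly across order blocks")
    rows = []
    for order in cfg.orders:
        pairs = [
            f"{c}+{v}" if order == "CV" else f"{v}+{c}"
            for c in cfg.consonants
            for v in cfg.vowels
        ]
        block: list[tuple[str, bool]] = []
        for flag, n_flag in ((True, counts.tms // n_blocks), (False, counts.control // n_blocks)):
            reps, extra = divmod(n_flag, len(pairs))
            chosen = list(pairs) * reps
            if extra:
                chosen += list(rng.choice(pairs, size=extra, replace=False))
            block += [(p, flag) for p in chosen]
        order_idx = rng.permutation(len(block))
        for i in order_idx:
            pair, flag = block[i]
            rows.append({"site": site, "order": order, "true_label": pair, "tms": flag})
    return pd.DataFrame(rows)


def _draw_response(
    true_label: str, hit_p: float, cfg: SessionConfig, rng: np.random.Generator
) -> tuple[str, float]:
    """Bernoulli hit; errors pick uniformly among the other consonants."""
    if rng.random() < cfg.p_miss:
        return MISSING, np.nan
    rt = float(rng.lognormal(mean=np.log(0.8), sigma=0.25))
    if rng.random() < hit_p:
        return true_label, rt
    a, b = true_label.split("+")
    true_c = a if a in cfg.consonants else b
    others = [c for c in cfg.consonants if c != true_c]
    wrong = str(rng.choice(others))
    resp = f"{wrong}+{b}" if a == true_c else f"{a}+{wrong}"
    return resp, rt


def _hit_probability(category: str, site: str, tms: bool, cfg: SessionConfig) -> float:
    if not tms:
        return cfg.behavioral_base_hit
    d = cfg.behavioral_congruency_delta
    if cfg.site_category.get(site) == category:
        p = cfg.behavioral_base_hit + d
    else:
        p = cfg.behavioral_base_hit - d
    return float(np.clip(p, 0.0, 1.0))


def _schedule_with_behavior(
    cfg: SessionConfig, participant: str, seed: np.random.SeedSequence
) -> pd.DataFrame:
    """Both runs' schedules plus behavioral draws (no EEG)."""
    ss_sched, ss_beh = seed.spawn(2)
    frames = []
    for site, child in zip(cfg.sites, ss_sched.spawn(len(cfg.sites))):
        frames.append(_run_schedule(cfg, site, np.random.default_rng(child)))
    sched = pd.concat(frames, ignore_index=True)
    rng = np.random.default_rng(ss_beh)
    cats, resps, rts, hits = [], [], [], []
    for _, row in sched.iterrows():
        a, b = row["true_label"].split("+")
        cons = a if a in cfg.consonants else b
        cat = CATEGORY_OF_CONSONANT.get(cons, "bilabial")
        p = _hit_probability(cat, row["site"], bool(row["tms"]), cfg)
        resp, rt = _draw_response(row["true_label"], p, cfg, rng)
        cats.append(cat)
        resps.append(resp)
        rts.append(rt)
        hits.append(resp == row["true_label"])
    sched["category"] = cats
    sched["response_label"] = resps
    sched["rt"] = rts
    sched["correct"] = hits
    sched.insert(0, "participant", participant)
    return sched


# ---------------------------------------------------------------------------
# full sessions


#: seconds of latent activity generated around each stimulus onset
TRIAL_SPAN = (-0.15, 0.65)
#: TMS pulse times relative to the (first) phoneme onset; the phoneme onset
#: coincides with the sound-stimulus onset, so the second pulse precedes it
PULSE_OFFSETS = (-0.100, -0.050)


def generate_session(
    cfg: SessionConfig,
    participant_id: str,
    seed: int | None = None,
    montage: Montage | None = None,
) -> Session:
    """Generate one participant's full session (both runs, one per site).

    Returns the continuous EEG record (float32, microvolts), the event
    table, and the behavioral response table.  Trials follow the run
    schedule at the configured inter-trial interval; every output is a
    deterministic function of ``(cfg, participant_id, seed)``.
    """
    montage = montage or default_montage()
    if len(montage.labels) != cfg.n_channels:
        raise ValueError(
            f"montage has {len(montage.labels)} channels, config wants {cfg.n_channels}"
        )
    root = np.random.SeedSequence([cfg.seed if seed is None else seed, _pid_key(participant_id)])
    ss_beh, ss_time, ss_bg, ss_trials = root.spawn(4)
    sched = _schedule_with_behavior(cfg, participant_id, ss_beh)

    fs = cfg.sample_rate
    rng_t = np.random.default_rng(ss_time)
    stim_times = []
    t = cfg.lead_time
    prev_site = sched.iloc[0]["site"]
    for _, row in sched.iterrows():
        if row["site"] != prev_site:
            t += cfg.run_gap
            prev_site = row["site"]
        stim_times.append(t)
        t += cfg.iti + rng_t.uniform(-cfg.iti_jitter, cfg.iti_jitter)
    span0, span1 = TRIAL_SPAN
    end_t = max(t, stim_times[-1] + span1) + cfg.lead_time
    n_samples = int(round(end_t * fs))

    data = np.zeros((cfg.n_channels, n_samples), dtype=np.float32)
    if cfg.pink_noise_scale > 0:
        bg = pink_noise(n_samples, np.random.default_rng(ss_bg), cfg.n_channels)
        bg *= np.float32(cfg.pink_noise_scale)
        data += bg

    n_trial = int(round((span1 - span0) * fs))
    trial_children = ss_trials.spawn(len(sched))
    # the record already carries continuous background noise; trials add signal only
    trial_cfg = replace(cfg, pink_noise_scale=0.0)
    weights = _mixing_weights(montage, cfg.motor_center, cfg.motor_sigma_mm)
    ev_rows = []
    for i, ((_, row), t_stim) in enumerate(zip(sched.iterrows(), stim_times)):
        tms = bool(row["tms"])
        trial = generate_trial_eeg(
            row["category"],
            row["site"],
            tms,
            trial_cfg,
            trial_children[i],
            n_trial,
            montage=montage,
            pulse_offsets_s=tuple(p - span0 for p in PULSE_OFFSETS),
            mixing_weights=weights,
        )
        i0 = int(round((t_stim + span0) * fs))
        lo = max(i0, 0)
        hi = min(i0 + n_trial, n_samples)
        data[:, lo:hi] += trial[:, lo - i0 : hi - i0].astype(np.float32)
        phon1 = t_stim  # phoneme onset coincides with the sound onset
        onsets = [phon1, phon1 + 0.2]
        ev_rows.append(
            {
                "trial_index": i,
                "t_tms_pulse2": phon1 + PULSE_OFFSETS[1] if tms else np.nan,
                "t_stim_onset": t_stim,
                "t_phoneme_onsets": onsets,
                "site": row["site"],
                "tms": tms,
                "order": row["order"],
                "true_label": row["true_label"],
                "response_label": row["response_label"],
                "rt": row["rt"],
            }
        )
    record = EEGRecord(sample_rate=fs, channels=montage.labels, data=data)
    events = EventTable(pd.DataFrame(ev_rows), tuple(cfg.inventory))
    behavior = sched[
        ["participant", "site", "tms", "order", "true_label", "response_label", "category", "correct", "rt"]
    ].copy()
    return Session(participant_id, record, events, behavior)


def _pid_key(participant_id: str) -> int:
    """Stable small integer derived from a participant id for seeding."""
    return int.from_bytes(str(participant_id).encode(), "little") % (2**31 - 1)


def generate_behavioral_cohort(
    cfg: SessionConfig, n_participants: int, seed: int | None = None
) -> pd.DataFrame:
    """Behavioral tables for a cohort (no EEG), concatenated.

    Per-participant substreams derive from the seed, so a cohort is
    reproducible and participants are independent.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    base = cfg.seed if seed is None else seed
    frames = []
    for i in range(n_participants):
        pid = f"S{i + 1:02d}"
        ss = np.random.SeedSequence([base, _pid_key(pid)]).spawn(4)[0]
        frames.append(_schedule_with_behavior(cfg, pid, ss))
    return pd.concat(frames, ignore_index=True)
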