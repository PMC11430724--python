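"""Channel triples and per-trial DDA feature matrices.

Decodable electrodes are partitioned into non-overlapping triples of
neighboring channels (20 triples for the default 60-channel decodable
set).  For each triple and sliding window we compute:

* three single-timeseries (ST) fits, one per channel, keeping their
  least-squares errors ``rho``;
* one cross-timeseries (CT) fit that stacks the three channels' design
  matrices and solves a single least-squares problem, keeping its
  coefficients and error; and
* a dynamical-ergodicity index, the ratio of the CT error to the mean ST
  error.  Channels sharing one latent dynamic fit jointly about as well
  as separately (index near 1); independent dynamics push the index up.

Per trial, the mean and standard deviation of each of the 8 per-window
quantities over all valid windows become the feature vector
(20 triples x 8 features x 2 statistics = 320 columns by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dda import DDAModelSpec, WindowConfig, _batched_design, window_count
from .io import Epoch, Montage

logger = logging.getLogger(__name__)

__all__ = [
    "ChannelTriple",
    "TripleFeatures",
    "TrialFeatureMatrix",
    "make_triples",
    "triple_features",
    "trial_feature_matrix",
]

FEATURE_FIELDS = (
    "ct_a1",
    "ct_a2",
    "ct_a3",
    "ct_rho",
    "st_rho1",
    "st_rho2",
    "st_rho3",
    "ergodicity",
)


@dataclass(frozen=True)
class ChannelTriple:
    channels: tuple[str, str, str]
    centroid: tuple[float, float, float]

    @property
    def name(self) -> str:
        return "+".join(self.channels)


def make_triples(montage: Montage) -> list[ChannelTriple]:
    """Greedy nearest-neighbor partition of the decodable set into triples.

    Repeatedly takes the unassigned channel farthest from the decodable
    set's centroid (most peripheral) and joins it with its two nearest
    unassigned neighbors.  Deterministic given the montage; ties break by
    label order.
    """
    labels = montage.decodable_labels
    if len(labels) % 3 != 0:
        raise ValueError(
            f"decodable channel count {len(labels)} not divisible by 3; "
            "adjust the montage's is_decodable flags"
        )
    pos = montage.positions(labels)
    center = pos.mean(axis=0)
    remaining = list(np.arange(len(labels)))
    triples: list[ChannelTriple] = []
    while remaining:
        rem = np.array(remaining)
        d_center = np.linalg.norm(pos[rem] - center, axis=1)
        # farthest from center; break ties toward lexicographically first label
        dmax = d_center.max()
        cand = rem[np.isclose(d_center, dmax)]
        seed_idx = min(cand, key=lambda i: labels[i])
        others = rem[rem != seed_idx]
        d = np.linalg.norm(pos[others] - pos[seed_idx], axis=1)
        take = others[np.lexsort(([labels[i] for i in others], np.round(d, 9)))][:2]
        group = sorted([seed_idx, *take], key=lambda i: labels[i])
        centroid = pos[group].mean(axis=0)
        triples.append(
            ChannelTriple(tuple(labels[i] for i in group), tuple(centroid))
        )
        for i in group:
            remaining.remove(i)
    return triples


@dataclass
class TripleFeatures:
    """Window-resolved DE-DDA features of one triple within one epoch."""

    triple: ChannelTriple
    window_start_times: np.ndarray
    ct_coeffs: np.ndarray  # (n_windows, 3)
    ct_rho: np.ndarray
    st_rhos: np.ndarray  # (n_windows, 3)
    ergodicity: np.ndarray

    def __len__(self) -> int:
        return len(self.ct_rho)

    @property
    def valid_mask(self) -> np.ndarray:
        return (
            np.all(np.isfinite(self.ct_coeffs), axis=1)
            & np.isfinite(self.ct_rho)
            & np.all(np.isfinite(self.st_rhos), axis=1)
            & np.isfinite(self.ergodicity)
        )

    def as_array(self) -> np.ndarray:
        """(n_windows, 8) array in FEATURE_FIELDS order."""
        return np.column_stack(
            [self.ct_coeffs, self.ct_rho, self.st_rhos, self.ergodicity]
        )


def _solve_gram(G: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched solve of normal equations with a pseudo-inverse fallback."""
    A = np.empty_like(b)
    with np.errstate(all="ignore"):
        try:
            A[:] = np.linalg.solve(G, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            A[:] = np.nan
    bad = ~np.all(np.isfinite(A), axis=-1)
    if bad.any():
        Ap = np.einsum("nij,nj->ni", np.linalg.pinv(G[bad]), b[bad])
        A[bad] = Ap
    return A


def _all_triple_features(
    data: np.ndarray,
    triples_idx: np.ndarray,
    spec: DDAModelSpec,
    wincfg: WindowConfig,
    normalize: bool,
    derivative: str,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Window features for every triple of one epoch in one batched pass.

    ``data`` is (n_channels, n_samples); ``triples_idx`` is (n_triples, 3)
    channel indices.  Returns ``(features, times, k_min)`` with
    ``features`` of shape (n_triples, n_windows, 8) in FEATURE_FIELDS
    order; windows before ``k_min`` lack a full lead-in and are NaN.
    """
    T = len(triples_idx)
    flat = np.asarray(triples_idx).reshape(-1)
    X = np.asarray(data, dtype=float)[flat]  # (3T, n_samples)
    w, s = wincfg.window_samples, wincfg.shift_samples
    m = spec.max_delay
    n = X.shape[1]
    n_win = window_count(n, w, s)
    times = np.arange(n_win) * s / wincfg.sample_rate
    feats = np.full((T, n_win, len(FEATURE_FIELDS)), np.nan)
    if n_win == 0:
        return feats, times, 0
    k_min = int(np.ceil(m / s))
    if k_min >= n_win:
        return feats, times, n_win
    L = w + m
    starts = np.arange(k_min, n_win) * s - m
    nv = starts.size
    segs = np.lib.stride_tricks.sliding_window_view(X, L, axis=1)[:, starts]
    M, y, valid = _batched_design(
        segs.reshape(-1, L), spec, wincfg.sample_rate, normalize, derivative
    )
    I = spec.n_terms
    R = M.shape[1]
    Mt = M.transpose(0, 2, 1)
    G = Mt @ M
    b = (Mt @ y[..., None])[..., 0]
    # single-timeseries fits per channel
    A_st = _solve_gram(G, b)
    r_st = y - (M @ A_st[..., None])[..., 0]
    rho_st = np.sqrt(np.mean(r_st * r_st, axis=1)).reshape(T, 3, nv)
    # cross-timeseries fit: stacked rows = summed normal equations
    G_ct = G.reshape(T, 3, nv, I, I).sum(axis=1).reshape(-1, I, I)
    b_ct = b.reshape(T, 3, nv, I).sum(axis=1).reshape(-1, I)
    A_ct = _solve_gram(G_ct, b_ct)  # (T*nv, I)
    A_rep = np.repeat(A_ct.reshape(T, 1, nv, I), 3, axis=1).reshape(-1, I)
    r_ct = y - (M @ A_rep[..., None])[..., 0]
    rho_ct = np.sqrt(
        np.mean((r_ct * r_ct).reshape(T, 3, nv, R), axis=(1, 3))
    )  # (T, nv)
    ok = valid.reshape(T, 3, nv).all(axis=1)  # any zero-variance channel flags window
    mean_st = rho_st.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        erg = np.where(mean_st > 0, rho_ct / mean_st, np.nan)
    block = np.concatenate(
        [
            A_ct.reshape(T, nv, I),
            rho_ct[..., None],
            np.moveaxis(rho_st, 1, 2),
            erg[..., None],
        ],
        axis=2,
    )
    block[~ok] = np.nan
    feats[:, k_min:] = block
    return feats, times, k_min


def triple_features(
    epoch: Epoch,
    triple: ChannelTriple,
    spec: DDAModelSpec = DDAModelSpec(),
    wincfg: WindowConfig | None = None,
    normalize: bool = True,
    derivative: str = "central",
) -> TripleFeatures:
    """ST and CT window fits plus the ergodicity index for one triple.

    The CT fit shares one coefficient vector across the triple by solving
    the three channels' stacked design matrices jointly; with per-channel
    normal equations this is the solve of the summed Gram matrices.
    Windows where any channel has zero variance are flagged NaN.
    """
    cfg = wincfg or WindowConfig(sample_rate=epoch.sample_rate)
    try:
        ch_idx = [epoch.channels.index(c) for c in triple.channels]
    except ValueError as exc:
        raise ValueError(f"epoch lacks a triple channel: {exc}") from exc
    feats, times, _ = _all_triple_features(
        epoch.data, np.array([ch_idx]), spec, cfg, normalize, derivative
    )
    f = feats[0]
    return TripleFeatures(
        triple, times, f[:, 0:3], f[:, 3], f[:, 4:7], f[:, 7]
    )


@dataclass
class TrialFeatureMatrix:
    """Per-trial feature vectors with trial labels and times.

    ``X`` holds the numeric features (rows ordered by trial time), ``meta``
    the aligned condition labels.  Trials whose windows were all flagged
    are dropped and counted in ``n_dropped``.
    """

    X: pd.DataFrame
    meta: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.X) != len(self.meta):
            raise ValueError("X and meta must align row-wise")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def subset(self, mask: np.ndarray) -> "TrialFeatureMatrix":
        return TrialFeatureMatrix(
            self.X.iloc[mask].reset_index(drop=True),
            self.meta.iloc[mask].reset_index(drop=True),
            self.n_dropped,
        )

    def to_csv(self, path) -> None:
        """Features + labels as one CSV with a JSON column-schema sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        merged = pd.concat([self.meta, self.X], axis=1)
        merged.to_csv(path, index=False)
        schema = {
            "meta_columns": list(self.meta.columns),
            "feature_columns": list(self.X.columns),
            "n_dropped": self.n_dropped,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(schema, indent=1))

    @classmethod
    def from_csv(cls, path) -> "TrialFeatureMatrix":
        import json
        from pathlib import Path

        path = Path(path)
        schema = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        merged = pd.read_csv(path)
        return cls(
            merged[schema["feature_columns"]],
            merged[schema["meta_columns"]],
            int(schema.get("n_dropped", 0)),
        )


def trial_feature_matrix(
    epochs: Sequence[Epoch],
    triples: Sequence[ChannelTriple],
    spec: DDAModelSpec = DDAModelSpec(),
    wincfg: WindowConfig | None = None,
    normalize: bool = True,
    derivative: str = "central",
) -> TrialFeatureMatrix:
    """Aggregate window features into one row per trial (mean and std).

    Rows are ordered by trial time; NaN-flagged windows are skipped in the
    aggregation and trials with no valid window at all are dropped (and
    counted).
    """
    if not epochs:
        raise ValueError("no epochs supplied")
    n_samp = epochs[0].n_samples
    chans = epochs[0].channels
    for e in epochs:
        if e.n_samples != n_samp or e.channels != chans:
            raise ValueError("all epochs must share channel set and length")
    cols: list[str] = []
    for tr in triples:
        for f in FEATURE_FIELDS:
            cols.append(f"{tr.name}|{f}|mean")
            cols.append(f"{tr.name}|{f}|std")
    cfg = wincfg or WindowConfig(sample_rate=epochs[0].sample_rate)
    try:
        triples_idx = np.array(
            [[chans.index(c) for c in tr.channels] for tr in triples]
        )
    except ValueError as exc:
        raise ValueError(f"epochs lack a triple channel: {exc}") from exc
    rows = []
    meta_rows = []
    dropped = 0
    for ep in epochs:
        feats, _, _ = _all_triple_features(
            ep.data, triples_idx, spec, cfg, normalize, derivative
        )
        ok = np.all(np.isfinite(feats), axis=2)  # (n_triples, n_windows)
        if not ok.any():
            dropped += 1
            continue
        vec = np.empty(len(cols))
        pos = 0
        for ti in range(len(triples)):
            sel = feats[ti][ok[ti]]
            if len(sel):
                mu, sd = sel.mean(axis=0), sel.std(axis=0)
            else:
                mu = sd = np.full(feats.shape[2], np.nan)
            vec[pos : pos + 16 : 2] = mu
            vec[pos + 1 : pos + 16 : 2] = sd
            pos += 16
        rows.append(vec)
        meta_rows.append({"trial_index": ep.trial_index, **ep.condition})
    if dropped:
        logger.info("trial_feature_matrix: dropped %d all-flagged trials", dropped)
    meta = pd.DataFrame(meta_rows)
    if "true_label" in meta.columns and len(meta):
        from .io import CATEGORY_OF_CONSONANT, pair_consonant

        cons = [pair_consonant(lab) for lab in meta["true_label"]]
        meta["phoneme"] = cons
        meta["category"] = [CATEGORY_OF_CONSONANT[c] for c in cons]
    X = pd.DataFrame(rows, columns=cols)
    if "t_stim_onset" in meta.columns and len(meta):
        idx = np.argsort(meta["t_stim_onset"].to_numpy(), kind="stable")
        X = X.iloc[idx].reset_index(drop=True)
        meta = meta.iloc[idx].reset_index(drop=True)
    # columns that are NaN for every trial would poison classifiers downstream
    return TrialFeatureMatrix(X, meta, dropped)
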