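"""Synthetic multi-day spiking datasets with phoneme-tuned articulatory drive.

The generative model emulates the statistics an attempted-speech decoding
pipeline has to absorb, without any biophysics:

* each electrode carries a linear tuning ``W`` (Hz per articulatory feature
  unit) to a latent articulatory trajectory ``a(t)`` — piecewise-constant
  phoneme feature vectors smoothed with a 60 ms moving average as a
  coarticulation proxy;
* firing rate ``rate(t) = softplus(b + W a(t) + day_offset + drift)``,
  guaranteeing nonnegative rates; attempted-silent trials attenuate the rate
  multiplicatively;
* threshold-crossing counts are Poisson over 20 ms bins; spike-band power is
  a noisy linear readout of the same rate (hence correlated with TX);
* non-stationarities: additive per-day rate offsets, optional random
  relabeling (permutation) of a subset of channels on later days, and a slow
  linear within-day drift along a fixed population direction;
* trials follow a delay/go structure: the articulatory drive is zero until
  the go cue.

Phoneme dwell times are log-normal (right-skewed, as real segment durations
are).  Everything is driven by explicit seeds; identical config + seed gives
identical datasets.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .articulation import ArticulatoryFeatureTable
from .phonemes import Lexicon, PhonemeInventory, sentence_to_labels


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclass
class SimConfig:
    """All distribution parameters of the generator, with units.

    Defaults describe a 64-electrode array with moderate articulatory tuning
    against a ~20 Hz multiunit baseline — rates in the tens of Hz so that
    20 ms Poisson bins carry usable but noisy evidence.
    """

    n_electrodes: int = 64
    bin_s: float = 0.02
    baseline_mean_hz: float = 20.0   # mean multiunit baseline rate
    baseline_sd_hz: float = 6.0
    tuning_sd_hz: float = 10.0       # s.d. of W entries, Hz per feature unit
    sbp_gain: float = 1.0            # SBP units per Hz
    sbp_noise_sd: float = 2.0        # additive Gaussian noise on SBP
    n_days: int = 1
    day_offset_sd_hz: float = 2.0    # additive across-day rate shifts
    permute_frac: float = 0.0        # fraction of channels relabeled per new day
    drift_hz_per_min: float = 0.05   # within-day linear drift magnitude
    silent_atten: float = 0.7        # rate multiplier in silent mode
    dwell_mean_s: float = 0.09       # mean phoneme dwell time
    dwell_log_sd: float = 0.4        # log-normal sigma of dwell times
    delay_s: float = 1.0             # instructed-delay epoch before go
    tail_s: float = 0.2              # trailing silence after last phoneme
    coart_bins: int = 3              # 60 ms moving-average coarticulation
    trial_gap_s: float = 10.0        # session time between trial starts
    poisson: bool = True             # False -> emit noiseless mean counts

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class TuningModel:
    """Electrode tuning, baselines and non-stationarity parameters."""

    W: np.ndarray                  # (n_electrodes, d) Hz per feature unit
    b: np.ndarray                  # (n_electrodes,) baseline Hz, >= 0
    day_offsets: np.ndarray        # (n_days, n_electrodes) additive Hz; row 0 zero
    day_perms: np.ndarray          # (n_days, n_electrodes) channel relabelings
    drift_dir: np.ndarray          # unit vector, fixed drift direction
    config: SimConfig

    def __post_init__(self):
        if np.any(self.b < 0):
            raise ValueError("baseline rates must be nonnegative")
        if not np.allclose(self.day_offsets[0], 0):
            raise ValueError("day 0 is the reference day (zero offsets)")

    @property
    def n_electrodes(self) -> int:
        return self.W.shape[0]


@dataclass
class TrialRecord:
    """One synthetic trial: features, labels and timing."""

    day: int
    mode: str                       # "vocal" | "silent"
    sentence: str
    labels: np.ndarray              # phoneme indices incl. SIL; no blanks
    tx: np.ndarray                  # (bins, n_electrodes) counts
    sbp: np.ndarray                 # (bins, n_electrodes) spike-band power
    go_bin: int
    frame_labels: np.ndarray        # (bins,) ground-truth phoneme index per bin
    trial_start_time: float         # minutes into session
    condition: Optional[str] = None  # set for instructed-delay tasks
    sentence_id: Optional[int] = None

    def __post_init__(self):
        if self.tx.shape != self.sbp.shape:
            raise ValueError("tx and sbp must share shape")
        if not (0 <= self.go_bin < self.tx.shape[0]):
            raise ValueError("go_bin outside trial")
        if len(self.frame_labels) != self.tx.shape[0]:
            raise ValueError("frame_labels length must equal n_bins")

    @property
    def n_bins(self) -> int:
        return self.tx.shape[0]


def make_tuning(
    n_electrodes: int,
    feature_table: ArticulatoryFeatureTable,
    config: SimConfig | None = None,
    seed: int = 0,
) -> TuningModel:
    """Draw a random tuning model (W zero-mean Gaussian, scaled by tuning_sd)."""
    if n_electrodes < 1:
        raise ValueError("need at least one electrode")
    config = config or SimConfig()
    config = dataclasses.replace(config, n_electrodes=n_electrodes)
    rng = np.random.default_rng(seed)
    d = feature_table.dim
    W = rng.normal(0.0, 1.0, size=(n_electrodes, d)) * config.tuning_sd_hz
    b = np.clip(
        rng.normal(config.baseline_mean_hz, config.baseline_sd_hz, n_electrodes),
        0.0, None,
    )
    day_offsets = np.zeros((config.n_days, n_electrodes))
    day_perms = np.tile(np.arange(n_electrodes), (config.n_days, 1))
    for k in range(1, config.n_days):
        day_offsets[k] = rng.normal(0.0, config.day_offset_sd_hz, n_electrodes)
        if config.permute_frac > 0:
            n_perm = max(2, int(round(config.permute_frac * n_electrodes)))
            idx = rng.choice(n_electrodes, size=n_perm, replace=False)
            day_perms[k, idx] = rng.permutation(idx)
    v = rng.normal(size=n_electrodes)
    drift_dir = v / np.linalg.norm(v)
    return TuningModel(W, b, day_offsets, day_perms, drift_dir, config)


def _dwell_bins(rng: np.random.Generator, n: int, cfg: SimConfig) -> np.ndarray:
    # log-normal with the configured arithmetic mean and log-sd
    mu = np.log(cfg.dwell_mean_s) - cfg.dwell_log_sd**2 / 2
    secs = rng.lognormal(mu, cfg.dwell_log_sd, size=n)
    return np.maximum(1, np.round(secs / cfg.bin_s).astype(int))


def _moving_average(x: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return x
    kernel = np.ones(k) / k
    pad = np.concatenate([np.repeat(x[:1], k - 1, axis=0), x], axis=0)
    out = np.empty_like(x, dtype=float)
    for j in range(x.shape[1]):
        out[:, j] = np.convolve(pad[:, j], kernel, mode="valid")
    return out


def trial_rate_curve(
    tuning: TuningModel,
    artic: np.ndarray,
    day: int,
    mode: str,
    trial_start_min: float,
) -> np.ndarray:
    """Ground-truth firing-rate curve (bins x electrodes, Hz)."""
    cfg = tuning.config
    drive = artic @ tuning.W.T  # (bins, E)
    drift = cfg.drift_hz_per_min * trial_start_min * tuning.drift_dir
    rate = softplus(tuning.b + drive + tuning.day_offsets[day] + drift)
    if mode == "silent":
        rate = rate * cfg.silent_atten
    return rate


def _emit(
    tuning: TuningModel,
    artic: np.ndarray,
    day: int,
    mode: str,
    trial_start_min: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    cfg = tuning.config
    rate = trial_rate_curve(tuning, artic, day, mode, trial_start_min)
    lam = rate * cfg.bin_s
    tx = rng.poisson(lam).astype(float) if cfg.poisson else lam
    sbp = cfg.sbp_gain * rate
    if cfg.sbp_noise_sd > 0:
        sbp = sbp + rng.normal(0.0, cfg.sbp_noise_sd, size=sbp.shape)
    perm = tuning.day_perms[day]
    return tx[:, perm], sbp[:, perm]


def synthesize_trial(
    sentence: str,
    tuning: TuningModel,
    feature_table: ArticulatoryFeatureTable,
    day: int,
    mode: str,
    lexicon: Lexicon,
    seed: int = 0,
    trial_start_min: float = 0.0,
    sentence_id: Optional[int] = None,
) -> TrialRecord:
    """Simulate one attempted-speech trial (delay epoch, then the sentence)."""
    if mode not in ("vocal", "silent"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = tuning.config
    inv = lexicon.inventory
    labels = np.asarray(sentence_to_labels(sentence, lexicon), dtype=int)
    rng = np.random.default_rng(seed)

    delay_bins = int(round(cfg.delay_s / cfg.bin_s))
    tail_bins = int(round(cfg.tail_s / cfg.bin_s))
    dwells = _dwell_bins(rng, len(labels), cfg)
    frame_labels = np.concatenate([
        np.full(delay_bins, inv.sil_index),
        np.repeat(labels, dwells),
        np.full(tail_bins, inv.sil_index),
    ])
    n_bins = len(frame_labels)

    d = feature_table.dim
    feats = np.zeros((inv.n_tokens, d))
    for i, ph in enumerate(inv.phonemes):
        feats[i] = feature_table.vector(ph)
    artic = feats[frame_labels]            # SIL/delay rows are zero
    artic = _moving_average(artic, cfg.coart_bins)

    tx, sbp = _emit(tuning, artic, day, mode, trial_start_min, rng)
    return TrialRecord(
        day=day, mode=mode, sentence=sentence, labels=labels,
        tx=tx, sbp=sbp, go_bin=delay_bins, frame_labels=frame_labels,
        trial_start_time=trial_start_min, sentence_id=sentence_id,
    )


def synthesize_dataset(
    sentences: Sequence[str],
    days: Sequence[int],
    tuning: TuningModel,
    feature_table: ArticulatoryFeatureTable,
    lexicon: Lexicon,
    seed: int = 0,
    mode: str = "vocal",
) -> Tuple[List[TrialRecord], Dict]:
    """Simulate a multi-day session: ``sentences`` spread evenly over ``days``.

    Trials within a day get increasing start times (``trial_gap_s`` apart).
    Returns the trials plus a manifest (seed, config hash, counts).
    """
    if len(sentences) == 0:
        raise ValueError("empty sentence list")
    days = list(days)
    cfg = tuning.config
    root = np.random.default_rng(seed)
    trial_seeds = root.integers(0, 2**31 - 1, size=len(sentences))
    trials: List[TrialRecord] = []
    per_day = int(np.ceil(len(sentences) / len(days)))
    for i, sent in enumerate(sentences):
        day = days[min(i // per_day, len(days) - 1)]
        within = i % per_day
        trials.append(synthesize_trial(
            sent, tuning, feature_table, day, mode, lexicon,
            seed=int(trial_seeds[i]),
            trial_start_min=within * cfg.trial_gap_s / 60.0,
            sentence_id=i,
        ))
    manifest = {
        "seed": int(seed),
        "config_hash": cfg.hash(),
        "config": cfg.to_dict(),
        "n_trials": len(trials),
        "days": sorted(set(days)),
        "mode": mode,
    }
    return trials, manifest


def synthesize_delay_task(
    conditions: Dict[str, np.ndarray] | Sequence[str],
    n_trials_per_condition: int,
    tuning: TuningModel,
    feature_table: ArticulatoryFeatureTable,
    seed: int = 0,
    movement_s: float = 1.5,
    day: int = 0,
    mode: str = "vocal",
) -> List[TrialRecord]:
    """Instructed-delay single-movement trials (cue -> delay -> go -> move).

    ``conditions`` is either a list of phoneme symbols (feature targets taken
    from the table) or an explicit mapping name -> feature vector.  The delay
    epoch sits at baseline (zero articulatory drive); the movement epoch
    holds the condition's target.
    """
    if not isinstance(conditions, dict):
        conditions = {ph: feature_table.vector(ph) for ph in conditions}
    if not conditions:
        raise ValueError("no conditions given")
    cfg = tuning.config
    rng = np.random.default_rng(seed)
    delay_bins = int(round(cfg.delay_s / cfg.bin_s))
    move_bins = int(round(movement_s / cfg.bin_s))
    n_bins = delay_bins + move_bins
    trials: List[TrialRecord] = []
    i = 0
    for name, target in conditions.items():
        for _ in range(n_trials_per_condition):
            artic = np.zeros((n_bins, feature_table.dim))
            artic[delay_bins:] = target
            artic = _moving_average(artic, cfg.coart_bins)
            t_min = i * cfg.trial_gap_s / 60.0
            tx, sbp = _emit(tuning, artic, day, mode, t_min, rng)
            trials.append(TrialRecord(
                day=day, mode=mode, sentence="", labels=np.empty(0, dtype=int),
                tx=tx, sbp=sbp, go_bin=delay_bins,
                frame_labels=np.full(n_bins, -1),
                trial_start_time=t_min, condition=name,
            ))
            i += 1
    return trials


def random_walk_day_offsets(tuning: TuningModel, step_sd_hz: float,
                            seed: int = 0) -> TuningModel:
    """Replace i.i.d. day offsets with a cumulative random walk.

    Gradual drift: day k's offset is day k-1's plus a Gaussian step, so
    nearby days stay more similar than distant ones (day 0 unchanged).
    """
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd_hz,
                       size=(tuning.config.n_days, tuning.n_electrodes))
    steps[0] = 0.0
    return dataclasses.replace(tuning, day_offsets=np.cumsum(steps, axis=0))


def random_condition_targets(
    n_conditions: int, dim: int, seed: int = 0, scale: float = 1.0
) -> Dict[str, np.ndarray]:
    """Distinct random feature targets for generic movement conditions."""
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n_conditions):
        v = rng.normal(size=dim)
        out[f"cond{i:03d}"] = scale * v / np.linalg.norm(v)
    return out
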