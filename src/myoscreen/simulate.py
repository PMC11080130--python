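"""Synthetic multichannel sEMG generation with motor-unit-level group structure.

Healthy and sarcopenic forearm muscle are emulated at the motor-unit (MU)
level. The accepted physiology of sarcopenia — denervation reduces the number
of MUs while reinnervation enlarges the survivors, and neuromuscular-junction
instability raises discharge jitter — maps onto four group contrast factors:

* ``mu_reduction`` (< 1): sarcopenic pools contain fewer MUs,
* ``amp_scale`` (> 1): their MUAPs are larger,
* ``jitter_scale`` (> 1): discharge timing is noisier,
* ``duration_scale`` (> 1): MUAP templates are longer, shifting spectral
  content downward.

Recruitment follows the size principle with a Fuglevand-style exponential
spread of thresholds and linear rate coding between recruitment and peak
rate. Discharges are renewal processes with Gaussian inter-spike intervals
(CV 0.15) plus per-discharge Gaussian jitter. MUAP templates are first
derivatives of a Gaussian, with channel-specific attenuation and delay around
each unit's territory. Trials mimic the grip protocol: three MVC contractions
plus sub-maximal force-tracking trials at 20% and 50% MVC, six channels at
2000 Hz.

Simulated AWGS measurements (grip, SMI, 5TCST) are drawn from group- and
sex-conditional Gaussians truncated at the AWGS 2019 cutoffs so that the
screening rule reproduces every subject's group label.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .stats import GRIP_CUTOFF, SMI_CUTOFF, TCST_CUTOFF, AWGSRecord, awgs_screen

CHANNEL_LABELS = ("BRA", "FCR", "FDS", "FCU", "ECU", "ED")
GROUPS = ("healthy", "sarcopenic")

# recruitment-range and amplitude-range constants of the Fuglevand-style pool
RECRUIT_RANGE = 40.0     # ratio of highest to lowest recruitment threshold
MAX_THRESHOLD = 0.75     # fraction of MVC at which the last MU is recruited
AMP_RANGE = 30.0         # ratio of largest to smallest MUAP amplitude
ISI_CV = 0.15            # coefficient of variation of inter-spike intervals
BASE_AMP = 0.05          # overall amplitude unit (arbitrary units)

# group- and sex-conditional AWGS measurement distributions: mean, SD of
# grip (kg), SMI (kg/m^2), 5TCST (s) for (group, sex)
AWGS_DISTRIBUTIONS = {
    ("healthy", "M"): ((34.1, 5.4), (7.7, 0.7), (10.3, 2.7)),
    ("healthy", "F"): ((22.4, 3.0), (6.4, 0.6), (9.7, 1.5)),
    ("sarcopenic", "M"): ((23.8, 2.2), (6.5, 0.3), (10.1, 3.3)),
    ("sarcopenic", "F"): ((14.4, 2.8), (5.1, 0.4), (10.9, 3.2)),
}
# fraction of male subjects per group
MALE_FRACTION = {"healthy": 16 / 45, "sarcopenic": 17 / 48}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and generator parameters.

    Group contrasts are expressed as multipliers applied to the healthy
    baseline when building a sarcopenic pool; setting all four to 1.0 yields
    a null dataset in which both groups share one generating process.
    """

    n_healthy: int = 45
    n_sarcopenic: int = 48
    fs: float = 2000.0                 # Hz
    n_channels: int = 6
    mvc_trials: int = 3
    submax_trials_per_level: int = 2
    levels: tuple[float, ...] = (0.20, 0.50)   # fractions of MVC
    trial_duration: float = 10.0       # s, sub-maximal force-tracking trials
    mvc_duration: float = 5.0          # s, MVC trials
    mu_count_mean: float = 120.0       # healthy pool size (Poisson mean)
    mu_reduction: float = 0.5          # sarcopenic MU count multiplier
    muap_amp_scale: float = 1.6        # sarcopenic MUAP amplitude multiplier
    jitter_sd_ms: float = 1.0          # healthy discharge jitter SD (ms)
    jitter_scale: float = 2.0          # sarcopenic jitter multiplier
    muap_duration_ms: tuple[float, float] = (1.5, 3.0)  # healthy sigma range
    duration_scale: float = 1.4        # sarcopenic MUAP duration multiplier
    firing_rate_range: tuple[float, float] = (8.0, 35.0)  # pulses/s
    noise_sd: float = 0.02             # additive white noise SD (a.u.)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_healthy", "n_sarcopenic", "n_channels", "mvc_trials",
                     "submax_trials_per_level"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not all(0 < lv < 1 for lv in self.levels):
            raise ValueError("levels must lie strictly between 0 and 1")
        if not self.fs > 2 * 500.0:
            raise ValueError("fs must exceed twice the 500 Hz analysis band")
        if self.jitter_sd_ms < 0 or self.noise_sd < 0:
            raise ValueError("jitter_sd_ms and noise_sd must be >= 0")
        if self.n_channels > len(CHANNEL_LABELS):
            raise ValueError(f"at most {len(CHANNEL_LABELS)} channels supported")

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return CHANNEL_LABELS[: self.n_channels]


@dataclass
class MUPool:
    """A recruited-ordered motor-unit pool for one simulated muscle."""

    thresholds: np.ndarray          # (n_mu,), fraction of MVC, ascending
    amplitudes: np.ndarray          # (n_mu,), > 0
    sigmas_ms: np.ndarray           # (n_mu,), MUAP Gaussian width
    jitter_sd_ms: float
    firing_rate_range: tuple[float, float]
    templates: list[np.ndarray]     # per MU: (n_channels, template_len)

    @property
    def n_mu(self) -> int:
        return self.thresholds.size

    def firing_rate(self, mu_index: int, level: float) -> float:
        """Linear rate coding between recruitment and peak rate."""
        r_min, r_max = self.firing_rate_range
        thr = self.thresholds[mu_index]
        gain = (r_max - r_min) / max(1.0 - thr, 0.1)
        return float(min(r_min + gain * max(level - thr, 0.0), r_max))


@dataclass
class RawRecording:
    """One trial of multichannel raw signal (channels x time, arbitrary units)."""

    subject_id: str
    trial_id: str
    level: str                       # "MVC" | "0.20" | "0.50" ...
    channel_labels: tuple[str, ...]
    samples: np.ndarray              # (n_channels, n_samples)
    fs: float

    def __post_init__(self) -> None:
        if self.samples.ndim != 2 or self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("samples must be (n_channels, n_samples)")


@dataclass
class Subject:
    subject_id: str
    group: str
    sex: str
    awgs: AWGSRecord
    trials: list[RawRecording] = field(default_factory=list)

    def trials_at(self, level: str) -> list[RawRecording]:
        return [t for t in self.trials if t.level == level]


@dataclass
class StudyDataset:
    config: SimulationConfig
    subjects: list[Subject]

    def __len__(self) -> int:
        return len(self.subjects)


def _muap_template(sigma_ms: float, amplitude: float, center_channel: float,
                   n_channels: int, fs: float) -> np.ndarray:
    """First derivative of a Gaussian, per channel delayed and attenuated with
    distance from the unit's territory center."""
    sigma = sigma_ms / 1000.0
    half = 4.0 * sigma
    t = np.arange(-half, half + 0.5 / fs, 1.0 / fs)
    rows = []
    for c in range(n_channels):
        dist = abs(c - center_channel)
        atten = np.exp(-dist / 1.0)
        delay = dist * 0.2e-3            # 0.2 ms per channel pitch
        tc = t - delay
        w = -(tc / sigma**2) * np.exp(-(tc**2) / (2 * sigma**2))
        peak = np.exp(-0.5) / sigma      # |w| maximum of the unit-amp shape
        rows.append(amplitude * atten * w / peak)
    return np.asarray(rows)


def build_mu_pool(config: SimulationConfig, group: str,
                  rng: np.random.Generator) -> MUPool:
    """Draw a motor-unit pool for one subject of the given group.

    Sarcopenic pools apply the config's contrast multipliers: fewer MUs,
    larger amplitudes, longer templates, noisier discharge timing. Recruitment
    thresholds follow an exponential ramp (size principle), so sorting them
    ascending fixes the recruitment order at every force level.
    """
    if group not in GROUPS:
        raise ValueError(f"invalid group label {group!r}")
    sarc = group == "sarcopenic"
    count_mean = config.mu_count_mean * (config.mu_reduction if sarc else 1.0)
    n_mu = max(1, int(rng.poisson(count_mean)))

    i = np.arange(1, n_mu + 1)
    thresholds = MAX_THRESHOLD * np.exp(np.log(RECRUIT_RANGE) * (i / n_mu - 1.0))
    thresholds = np.sort(thresholds)

    amp_scale = config.muap_amp_scale if sarc else 1.0
    amplitudes = BASE_AMP * amp_scale * np.exp(np.log(AMP_RANGE) * i / n_mu) / AMP_RANGE

    lo, hi = config.muap_duration_ms
    dur_scale = config.duration_scale if sarc else 1.0
    sigmas = rng.uniform(lo, hi, size=n_mu) * dur_scale

    centers = rng.uniform(0.0, config.n_channels - 1.0, size=n_mu)
    templates = [
        _muap_template(sigmas[k], amplitudes[k], centers[k],
                       config.n_channels, config.fs)
        for k in range(n_mu)
    ]
    jitter = config.jitter_sd_ms * (config.jitter_scale if sarc else 1.0)
    return MUPool(thresholds, amplitudes, sigmas, jitter,
                  config.firing_rate_range, templates)


def _spike_times(rate: float, duration: float, jitter_sd_s: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Renewal discharge train: Gaussian ISIs (CV 0.15), plus timing jitter."""
    mean_isi = 1.0 / rate
    n_expect = int(duration * rate * 1.5) + 5
    isis = rng.normal(mean_isi, ISI_CV * mean_isi, size=n_expect)
    isis = np.clip(isis, 0.2 * mean_isi, None)
    times = rng.uniform(0.0, mean_isi) + np.cumsum(isis)
    while times.size and times[-1] < duration:   # pragma: no cover - rare top-up
        extra = np.clip(rng.normal(mean_isi, ISI_CV * mean_isi, size=n_expect),
                        0.2 * mean_isi, None)
        times = np.concatenate([times, times[-1] + np.cumsum(extra)])
    times = times + rng.normal(0.0, jitter_sd_s, size=times.size)
    return times[(times >= 0.0) & (times < duration)]


def generate_trial(pool: MUPool, level: float, config: SimulationConfig,
                   rng: np.random.Generator, duration: float | None = None,
                   subject_id: str = "S?", trial_id: str = "t?",
                   level_tag: str | None = None) -> RawRecording:
    """Superpose jittered MUAP trains of all recruited units plus white noise."""
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    duration = config.trial_duration if duration is None else duration
    n_samples = int(round(duration * config.fs))
    signal = np.zeros((config.n_channels, n_samples))

    active = np.flatnonzero(pool.thresholds <= level)
    if active.size == 0 and pool.n_mu > 0:
        warnings.warn(f"level {level} recruits no motor units; noise-only trial",
                      stacklevel=2)
    jitter_s = pool.jitter_sd_ms / 1000.0
    for k in active:
        rate = pool.firing_rate(k, level)
        tmpl = pool.templates[k]
        tlen = tmpl.shape[1]
        for t in _spike_times(rate, duration, jitter_s, rng):
            start = int(round(t * config.fs)) - tlen // 2
            lo = max(start, 0)
            hi = min(start + tlen, n_samples)
            if hi <= lo:
                continue
            signal[:, lo:hi] += tmpl[:, lo - start : hi - start]
    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=signal.shape)
    tag = level_tag if level_tag is not None else f"{level:.2f}"
    return RawRecording(subject_id, trial_id, tag, config.channel_labels,
                        signal, config.fs)


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float,
                    low: float | None = None, high: float | None = None) -> float:
    """Rejection-sample a Gaussian truncated to [low, high); falls back to the
    nearest bound interior after 1000 tries (never hit for the study means)."""
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x <= 0:
            continue
        if low is not None and x < low:
            continue
        if high is not None and x >= high:
            continue
        return float(x)
    return float(low + 0.1 if low is not None else high - 0.1)  # pragma: no cover


def _draw_awgs(group: str, sex: str, rng: np.random.Generator) -> AWGSRecord:
    (g_mu, g_sd), (s_mu, s_sd), (t_mu, t_sd) = AWGS_DISTRIBUTIONS[(group, sex)]
    if group == "healthy":
        grip = _draw_truncated(rng, g_mu, g_sd, low=GRIP_CUTOFF[sex])
        smi = _draw_truncated(rng, s_mu, s_sd, low=SMI_CUTOFF[sex])
        tcst = _draw_truncated(rng, t_mu, t_sd, high=TCST_CUTOFF)
    else:
        # low mass plus low strength guarantees the sarcopenic label
        grip = _draw_truncated(rng, g_mu, g_sd, high=GRIP_CUTOFF[sex])
        smi = _draw_truncated(rng, s_mu, s_sd, high=SMI_CUTOFF[sex])
        tcst = _draw_truncated(rng, t_mu, t_sd)
    return AWGSRecord(sex, grip, smi, tcst)


def generate_dataset(config: SimulationConfig) -> StudyDataset:
    """Generate the full study: per subject a MU pool, simulated AWGS
    measurements consistent with the group label, three MVC trials and the
    configured sub-maximal trials per force level. Deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    subjects: list[Subject] = []
    plan = [("healthy", config.n_healthy, "H"), ("sarcopenic", config.n_sarcopenic, "S")]
    for group, n, prefix in plan:
        for idx in range(n):
            sid = f"{prefix}{idx + 1:03d}"
            sex = "M" if rng.random() < MALE_FRACTION[group] else "F"
            awgs = _draw_awgs(group, sex, rng)
            label = awgs_screen(awgs)
            if label != group:      # pragma: no cover - precluded by truncation
                raise RuntimeError(f"AWGS draw inconsistent with group for {sid}")
            pool = build_mu_pool(config, group, rng)
            subject = Subject(sid, group, sex, awgs)
            for m in range(config.mvc_trials):
                subject.trials.append(
                    generate_trial(pool, 1.0, config, rng,
                                   duration=config.mvc_duration,
                                   subject_id=sid, trial_id=f"mvc{m + 1}",
                                   level_tag="MVC"))
            for level in config.levels:
                for r in range(config.submax_trials_per_level):
                    tag = f"{level:.2f}"
                    subject.trials.append(
                        generate_trial(pool, level, config, rng,
                                       subject_id=sid,
                                       trial_id=f"lv{tag}_{r + 1}",
                                       level_tag=tag))
            subjects.append(subject)
    return StudyDataset(config, subjects)


# ---------------------------------------------------------------------------
# plain-text persistence: one CSV per trial plus a YAML manifest


def write_dataset(dataset: StudyDataset, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"fs": dataset.config.fs, "subjects": []}
    for subj in dataset.subjects:
        entry = {
            "id": subj.subject_id, "group": subj.group, "sex": subj.sex,
            "grip_kg": subj.awgs.grip_kg, "smi_kg_m2": subj.awgs.smi_kg_m2,
            "tcst_s": subj.awgs.tcst_s, "trials": [],
        }
        sdir = out / subj.subject_id
        sdir.mkdir(exist_ok=True)
        for trial in subj.trials:
            rel = f"{subj.subject_id}/{trial.trial_id}.csv"
            with open(out / rel, "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(trial.channel_labels)
                w.writerows(trial.samples.T.tolist())
            entry["trials"].append({"path": rel, "level": trial.level,
                                    "id": trial.trial_id})
        manifest["subjects"].append(entry)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return out / "manifest.yaml"


def read_dataset(manifest_path: str | Path,
                 config: SimulationConfig | None = None) -> StudyDataset:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    fs = float(manifest["fs"])
    subjects = []
    for entry in manifest["subjects"]:
        awgs = AWGSRecord(entry["sex"], entry["grip_kg"], entry["smi_kg_m2"],
                          entry["tcst_s"])
        subj = Subject(entry["id"], entry["group"], entry["sex"], awgs)
        for tr in entry["trials"]:
            with open(root / tr["path"], newline="") as fh:
                reader = csv.reader(fh)
                labels = tuple(next(reader))
                data = np.array([[float(v) for v in row] for row in reader]).T
            subj.trials.append(RawRecording(entry["id"], tr["id"], tr["level"],
                                            labels, data, fs))
        subjects.append(subj)
    cfg = config if config is not None else SimulationConfig(
        n_healthy=max(1, sum(s.group == "healthy" for s in subjects)),
        n_sarcopenic=max(1, sum(s.group == "sarcopenic" for s in subjects)),
        fs=fs, n_channels=len(subjects[0].trials[0].channel_labels))
    return StudyDataset(cfg, subjects)
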