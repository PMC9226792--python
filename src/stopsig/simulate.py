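"""Synthetic study generator: race-model behavior and template-based EEG.

Behavior follows the independent horse-race model of response inhibition:
on every trial each hand has a latent go finish time (ex-Gaussian); on stop
trials a stop process with latency SSRT starts at the stop-signal onset and
the cued hand is withheld iff ``ssd + ssrt < go_finish`` (and the stop
process triggered at all).  Proactive preparation enters as an additive
slowing of go finish times on proactive trials; group differences in
stopping are injected through the stop-latency parameters.

EEG is a minimal generative model sufficient to exercise windowed peak
extraction: each event class adds a Gaussian-in-time component at a fixed
latency with per-channel scalp weights, on top of 1/f-like background
noise, stereotyped biphasic blinks mirrored on the EOG channel, and
occasional gross high-amplitude artifacts.  With noise and artifacts
disabled each epoch equals its template exactly, which downstream modules
exploit for round-trip tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task_design import DesignParams, TaskSchedule, TrialSpec, generate_schedule

__all__ = [
    "ParameterError",
    "RaceModelParams",
    "ComponentTemplate",
    "ErpTemplateParams",
    "BehavioralTrial",
    "SimulatedSession",
    "simulate_behavior",
    "simulate_eeg",
    "simulate_session",
    "simulate_study",
    "simulate_measures",
    "default_group_params",
    "EEG_CHANNELS",
    "EOG_CHANNEL",
    "ALL_CHANNELS",
    "SFREQ",
]

EEG_CHANNELS = ("Fz", "F3", "F4", "Cz", "C3", "C4")
EOG_CHANNEL = "EOG"
ALL_CHANNELS = EEG_CHANNELS + (EOG_CHANNEL,)
SFREQ = 500.0  # Hz

FRONTAL = ("Fz", "F3", "F4")
CENTRAL = ("Cz", "C3", "C4")


class ParameterError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class RaceModelParams:
    """Latent parameters of the independent race between go and stop.

    Go finish times are ex-Gaussian (mu, sigma, tau, in ms); the observable
    mean go RT is ``mu + tau``.  Stop latencies are Gaussian truncated at
    zero, per condition, so SSRT estimates can differ between reactive and
    proactive stopping.  ``proactive_slowing_ms`` shifts go finish times on
    proactive trials only.
    """

    go_mu: float = 560.0
    go_sigma: float = 50.0
    go_tau: float = 170.0
    stop_mu_reactive: float = 345.0
    stop_mu_proactive: float = 340.0
    stop_sigma: float = 30.0
    proactive_slowing_ms: float = 10.0
    trigger_failure_p: float = 0.02
    choice_error_p: float = 0.08
    go_omission_p: float = 0.05

    def validate(self) -> None:
        if min(self.go_sigma, self.go_tau, self.stop_sigma) <= 0:
            raise ParameterError("scale parameters must be > 0")
        if min(self.go_mu, self.stop_mu_reactive, self.stop_mu_proactive) <= 0:
            raise ParameterError("location parameters must be > 0")
        for name in ("trigger_failure_p", "choice_error_p", "go_omission_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{name}={p} outside [0, 1]")
        if self.proactive_slowing_ms < 0:
            raise ParameterError("proactive_slowing_ms must be >= 0")

    def stop_mu(self, condition: str) -> float:
        return (self.stop_mu_proactive if condition == "proactive"
                else self.stop_mu_reactive)


@dataclass(frozen=True)
class ComponentTemplate:
    """One ERP component: a Gaussian bump in time with scalp weights."""

    peak_latency_ms: float
    peak_amplitude_uv: float        # signed; negative for N2
    width_ms: float = 40.0          # Gaussian SD
    scalp_weights: dict[str, float] = field(default_factory=dict)

    def waveform(self, times_ms: np.ndarray) -> np.ndarray:
        return self.peak_amplitude_uv * np.exp(
            -0.5 * ((times_ms - self.peak_latency_ms) / self.width_ms) ** 2)


def _frontal_weights() -> dict[str, float]:
    return {ch: 1.0 for ch in FRONTAL}


def _central_weights() -> dict[str, float]:
    return {ch: 1.0 for ch in CENTRAL}


@dataclass(frozen=True)
class ErpTemplateParams:
    """Templates for the four components plus noise/artifact settings.

    Component peak latencies sit inside their measurement search windows by
    construction (P3 cue 300-550 ms, P3 go/stop 280-500 ms, N2 stop
    200-350 ms).  Scalp weights keep frontal (P3 cue, N2 stop) and central
    (P3 go, P3 stop) components on disjoint channels so that a noiseless
    simulation reproduces each template exactly at its own electrodes.
    """

    p3cue: ComponentTemplate = field(default_factory=lambda: ComponentTemplate(
        400.0, 3.5, 45.0, _frontal_weights()))
    p3go: ComponentTemplate = field(default_factory=lambda: ComponentTemplate(
        380.0, 2.2, 45.0, _central_weights()))
    n2stop: ComponentTemplate = field(default_factory=lambda: ComponentTemplate(
        270.0, -1.5, 30.0, _frontal_weights()))
    p3stop: ComponentTemplate = field(default_factory=lambda: ComponentTemplate(
        380.0, 3.2, 45.0, _central_weights()))
    noise_rms_uv: float = 8.0
    noise_exponent: float = 1.0        # power ~ 1/f^exponent
    blink_rate_per_min: float = 4.0
    blink_amplitude_uv: float = 90.0
    gross_artifact_p: float = 0.03
    gross_artifact_uv: float = 150.0

    def validate(self) -> None:
        if self.n2stop.peak_amplitude_uv >= 0:
            raise ParameterError("N2 stop amplitude must be negative")
        for name in ("p3cue", "p3go", "p3stop"):
            if getattr(self, name).peak_amplitude_uv <= 0:
                raise ParameterError(f"{name} amplitude must be positive")
        if not 300 <= self.p3cue.peak_latency_ms <= 550:
            raise ParameterError("p3cue latency outside its 300-550 ms window")
        for name in ("p3go", "p3stop"):
            if not 280 <= getattr(self, name).peak_latency_ms <= 500:
                raise ParameterError(f"{name} latency outside its 280-500 ms window")
        if not 200 <= self.n2stop.peak_latency_ms <= 350:
            raise ParameterError("n2stop latency outside its 200-350 ms window")
        if self.noise_rms_uv < 0 or self.blink_rate_per_min < 0:
            raise ParameterError("noise/blink settings must be >= 0")
        if not 0.0 <= self.gross_artifact_p <= 1.0:
            raise ParameterError("gross_artifact_p outside [0, 1]")

    def component(self, name: str) -> ComponentTemplate:
        return {"P3cue": self.p3cue, "P3go": self.p3go,
                "N2stop": self.n2stop, "P3stop": self.p3stop}[name]


@dataclass(frozen=True)
class BehavioralTrial:
    """Observed outcome of one trial.

    RTs are measured from go-stimulus onset; an absent response is nan.
    Classification is one of go_correct / go_omission / stop_success /
    stop_failed / stop_choice_error.
    """

    index: int
    condition: str
    trial_type: str
    cue_direction: str
    stop_direction: str
    ssd_ms: float
    left_rt_ms: float
    right_rt_ms: float
    classification: str


@dataclass
class SimulatedSession:
    """One subject's full session: schedule, behavior, continuous EEG."""

    schedule: TaskSchedule
    behavior: list[BehavioralTrial]
    eeg_uv: np.ndarray                  # channels x samples, microvolts
    ch_names: tuple[str, ...]
    sfreq: float
    events: pd.DataFrame                # onset_sample, code, condition, direction, ssd_ms
    race_params: RaceModelParams
    erp_params: ErpTemplateParams
    blink_intervals: list[tuple[int, int]] = field(default_factory=list)
    artifact_trials: list[int] = field(default_factory=list)
    subject_id: str = "sub-00"
    group: str = ""


def _exgauss(rng: np.random.Generator, mu: float, sigma: float, tau: float,
             size: int | None = None) -> np.ndarray | float:
    return rng.normal(mu, sigma, size) + rng.exponential(tau, size)


def _truncnorm_pos(rng: np.random.Generator, mu: float, sigma: float) -> float:
    for _ in range(100):
        v = rng.normal(mu, sigma)
        if v > 0:
            return v
    return abs(rng.normal(mu, sigma))  # pathological sigma >> mu


def simulate_behavior(schedule: TaskSchedule, params: RaceModelParams,
                      seed: int = 0) -> list[BehavioralTrial]:
    """Run the independent race model over a schedule.

    Go trials produce bimanual RTs (independent ex-Gaussian draws per hand,
    plus the proactive slowing shift on proactive trials) or a full
    omission.  On stop trials the cued hand is withheld iff the stop
    process, starting at ssd, beats that hand's go finish time and no
    trigger failure occurs; an uninhibited stop trial is a failed stop
    (both hands respond) with probability 1 - choice_error_p, or a choice
    error (only the to-be-stopped hand responds) otherwise.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    trials: list[BehavioralTrial] = []
    for t in schedule:
        slowing = params.proactive_slowing_ms if t.condition == "proactive" else 0.0
        finish = {h: float(_exgauss(rng, params.go_mu, params.go_sigma,
                                    params.go_tau)) + slowing
                  for h in ("left", "right")}
        # Attention lapses are trial-level and do not switch off on stop
        # trials: a lapsed stop trial produces no response at all (scored a
        # successful stop), which is exactly the failure mode the SSRT
        # estimator's omission-replacement rule corrects for.
        lapse = rng.random() < params.go_omission_p
        if t.trial_type == "go":
            if lapse:
                cls, left, right = "go_omission", math.nan, math.nan
            else:
                cls, left, right = "go_correct", finish["left"], finish["right"]
        elif lapse:
            cls, left, right = "stop_success", math.nan, math.nan
        else:
            cued = t.stop_direction
            other = "right" if cued == "left" else "left"
            ssrt = _truncnorm_pos(rng, params.stop_mu(t.condition), params.stop_sigma)
            triggered = rng.random() >= params.trigger_failure_p
            inhibited = triggered and (t.ssd_ms + ssrt < finish[cued])
            rts = {"left": math.nan, "right": math.nan}
            if inhibited:
                cls = "stop_success"
                rts[other] = finish[other]
            elif rng.random() < params.choice_error_p:
                cls = "stop_choice_error"
                rts[cued] = finish[cued]
            else:
                cls = "stop_failed"
                rts[cued] = finish[cued]
                rts[other] = finish[other]
            left, right = rts["left"], rts["right"]
        trials.append(BehavioralTrial(
            index=t.index, condition=t.condition, trial_type=t.trial_type,
            cue_direction=t.cue_direction, stop_direction=t.stop_direction,
            ssd_ms=t.ssd_ms, left_rt_ms=left, right_rt_ms=right,
            classification=cls))
    return trials


def behavior_to_frame(behavior: list[BehavioralTrial]) -> pd.DataFrame:
    return pd.DataFrame([vars(b) for b in behavior])


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                rms: float, exponent: float) -> np.ndarray:
    """Gaussian noise with power spectral density ~ 1/f^exponent, scaled to
    the requested per-channel RMS."""
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    freqs = np.fft.rfftfreq(n_samples, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = (rng.standard_normal((n_channels, freqs.size))
            + 1j * rng.standard_normal((n_channels, freqs.size))) * scale
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    x *= rms / np.sqrt(np.mean(x ** 2, axis=1, keepdims=True))
    return x


def _blink_waveform(sfreq: float) -> np.ndarray:
    """Stereotyped 400 ms biphasic blink: large positive lobe followed by a
    smaller negative rebound (unit peak amplitude)."""
    n = int(round(0.4 * sfreq))
    t = np.arange(n) / sfreq
    pos = np.sin(np.pi * np.clip(t / 0.25, 0, 1)) ** 2
    neg = -0.3 * np.sin(np.pi * np.clip((t - 0.25) / 0.15, 0, 1)) ** 2
    return pos + neg


BLINK_TOPOGRAPHY = {"Fz": 0.45, "F3": 0.35, "F4": 0.35,
                    "Cz": 0.12, "C3": 0.08, "C4": 0.08, EOG_CHANNEL: 1.0}

# Event codes in the marker table.
EVENT_CODES = {"cue": 1, "go": 2, "stop": 3, "response": 4}


def simulate_eeg(schedule: TaskSchedule, behavior: list[BehavioralTrial],
                 templates: ErpTemplateParams, seed: int = 0) -> SimulatedSession:
    """Synthesize a continuous multichannel record around a schedule.

    Channels are Fz F3 F4 Cz C3 C4 plus EOG, at 500 Hz.  Component
    templates are added time-locked to their events: P3 cue at cue onset,
    P3 go at go-stimulus onset on go trials, N2/P3 stop at stop-signal
    onset on stop trials.  The returned session records ground truth
    (blink sample intervals, artifact-bearing trial indices) for tests.
    """
    templates.validate()
    if len(behavior) != len(schedule.trials):
        raise ParameterError("behavior not aligned to schedule")
    rng = np.random.default_rng(seed)
    sfreq = SFREQ
    params = schedule.design_params
    trial_len_s = params.trial_duration_ms / 1000.0
    pad_s = 1.0
    n_samples = int(round((len(schedule) * trial_len_s + 2 * pad_s) * sfreq))
    n_ch = len(ALL_CHANNELS)
    ch_index = {ch: i for i, ch in enumerate(ALL_CHANNELS)}

    data = _pink_noise(rng, n_ch, n_samples, templates.noise_rms_uv,
                       templates.noise_exponent)

    def add_component(tpl: ComponentTemplate, onset_sample: int) -> None:
        dur = int(round((tpl.peak_latency_ms + 6 * tpl.width_ms) / 1000.0 * sfreq))
        idx = np.arange(onset_sample, min(onset_sample + dur, n_samples))
        times_ms = (idx - onset_sample) / sfreq * 1000.0
        wave = tpl.waveform(times_ms)
        for ch, w in tpl.scalp_weights.items():
            data[ch_index[ch], idx] += w * wave

    events: list[dict] = []
    artifact_trials: list[int] = []
    for t, b in zip(schedule.trials, behavior):
        t0 = int(round((pad_s + t.index * trial_len_s) * sfreq))
        cue_s = t0
        stim_s = t0 + int(round(t.stimulus_onset_ms / 1000.0 * sfreq))
        events.append(dict(onset_sample=cue_s, code=EVENT_CODES["cue"],
                           event="cue", condition=t.condition,
                           direction=t.cue_direction, ssd_ms=t.ssd_ms,
                           trial_index=t.index, trial_type=t.trial_type))
        add_component(templates.p3cue, cue_s)
        if t.trial_type == "go":
            events.append(dict(onset_sample=stim_s, code=EVENT_CODES["go"],
                               event="go", condition=t.condition,
                               direction="both", ssd_ms=math.nan,
                               trial_index=t.index, trial_type="go"))
            add_component(templates.p3go, stim_s)
        else:
            stop_s = stim_s + int(round(t.ssd_ms / 1000.0 * sfreq))
            events.append(dict(onset_sample=stim_s, code=EVENT_CODES["go"],
                               event="go", condition=t.condition,
                               direction="both", ssd_ms=math.nan,
                               trial_index=t.index, trial_type="stop"))
            events.append(dict(onset_sample=stop_s, code=EVENT_CODES["stop"],
                               event="stop", condition=t.condition,
                               direction=t.stop_direction, ssd_ms=t.ssd_ms,
                               trial_index=t.index, trial_type="stop"))
            add_component(templates.n2stop, stop_s)
            add_component(templates.p3stop, stop_s)
        for hand, rt in (("left", b.left_rt_ms), ("right", b.right_rt_ms)):
            if not math.isnan(rt):
                events.append(dict(
                    onset_sample=stim_s + int(round(rt / 1000.0 * sfreq)),
                    code=EVENT_CODES["response"], event="response",
                    condition=t.condition, direction=hand, ssd_ms=math.nan,
                    trial_index=t.index, trial_type=t.trial_type))
        # Gross artifact: a high-amplitude square pulse inside the epoch
        # window of this trial's stimulus, on one random scalp channel.
        if rng.random() < templates.gross_artifact_p:
            artifact_trials.append(t.index)
            ch = rng.integers(len(EEG_CHANNELS))
            a0 = stim_s + int(round(0.1 * sfreq))
            a1 = min(a0 + int(round(0.2 * sfreq)), n_samples)
            data[ch, a0:a1] += templates.gross_artifact_uv * rng.choice([-1.0, 1.0])

    blink_intervals: list[tuple[int, int]] = []
    if templates.blink_rate_per_min > 0 and templates.blink_amplitude_uv > 0:
        wave = _blink_waveform(sfreq)
        n_blinks = rng.poisson(templates.blink_rate_per_min
                               * (n_samples / sfreq) / 60.0)
        starts = np.sort(rng.integers(0, n_samples - wave.size,
                                      size=int(n_blinks)))
        for s in starts:
            s = int(s)
            amp = templates.blink_amplitude_uv * rng.uniform(0.8, 1.2)
            for ch, w in BLINK_TOPOGRAPHY.items():
                data[ch_index[ch], s:s + wave.size] += amp * w * wave
            blink_intervals.append((s, s + wave.size))

    ev = pd.DataFrame(events).sort_values("onset_sample", kind="stable")
    ev = ev.reset_index(drop=True)
    return SimulatedSession(
        schedule=schedule, behavior=behavior, eeg_uv=data,
        ch_names=ALL_CHANNELS, sfreq=sfreq, events=ev,
        race_params=RaceModelParams(), erp_params=templates,
        blink_intervals=blink_intervals, artifact_trials=artifact_trials)


def simulate_session(design: DesignParams | None = None,
                     race: RaceModelParams | None = None,
                     templates: ErpTemplateParams | None = None,
                     seed: int = 0, subject_id: str = "sub-00",
                     group: str = "") -> SimulatedSession:
    """One subject end to end: schedule -> behavior -> EEG."""
    race = race or RaceModelParams()
    templates = templates or ErpTemplateParams()
    rng = np.random.default_rng(seed)
    s_sched, s_beh, s_eeg = (int(rng.integers(2 ** 31)) for _ in range(3))
    schedule = generate_schedule(design, seed=s_sched)
    behavior = simulate_behavior(schedule, race, seed=s_beh)
    session = simulate_eeg(schedule, behavior, templates, seed=s_eeg)
    session.race_params = race
    session.subject_id = subject_id
    session.group = group
    return session


def default_group_params() -> dict[str, tuple[RaceModelParams, ErpTemplateParams]]:
    """Study-condition defaults for the two groups.

    Gamers (``vga``) respond faster on go trials, show slowed proactive
    stopping and more choice errors, a smaller cue-locked P3, a shallower
    stop-locked N2 and a larger stop-locked P3; controls follow the base
    parameter set.  Magnitudes follow the group means the reference study
    reports (go RT ~650 vs ~730 ms; proactive SSRT ~380 vs ~340 ms; P3 cue
    ~2.2 vs ~3.9 uV; proactive N2 ~-1.1 vs ~-2.3 uV; proactive stop P3
    ~3.9 vs ~2.8 uV).
    """
    control_race = RaceModelParams()
    vga_race = replace(control_race, go_mu=480.0, stop_mu_proactive=380.0,
                       stop_mu_reactive=350.0, choice_error_p=0.13)
    control_erp = ErpTemplateParams(
        p3cue=ComponentTemplate(400.0, 3.9, 45.0, _frontal_weights()),
        n2stop=ComponentTemplate(270.0, -2.3, 30.0, _frontal_weights()),
        p3stop=ComponentTemplate(380.0, 2.8, 45.0, _central_weights()))
    vga_erp = ErpTemplateParams(
        p3cue=ComponentTemplate(400.0, 2.2, 45.0, _frontal_weights()),
        n2stop=ComponentTemplate(270.0, -1.1, 30.0, _frontal_weights()),
        p3stop=ComponentTemplate(380.0, 3.9, 45.0, _central_weights()))
    return {"control": (control_race, control_erp),
            "vga": (vga_race, vga_erp)}


def _jitter_race(rng: np.random.Generator, p: RaceModelParams,
                 sd_ms: float) -> RaceModelParams:
    return replace(
        p,
        go_mu=max(100.0, p.go_mu + rng.normal(0, sd_ms)),
        stop_mu_reactive=max(50.0, p.stop_mu_reactive + rng.normal(0, sd_ms)),
        stop_mu_proactive=max(50.0, p.stop_mu_proactive + rng.normal(0, sd_ms)),
    )


def _jitter_erp(rng: np.random.Generator, p: ErpTemplateParams,
                sd_uv: float) -> ErpTemplateParams:
    def bump(tpl: ComponentTemplate, sign: float) -> ComponentTemplate:
        amp = tpl.peak_amplitude_uv + rng.normal(0, sd_uv)
        # keep the component's polarity
        amp = sign * max(0.2, sign * amp)
        lat = tpl.peak_latency_ms + rng.normal(0, 10.0)
        return replace(tpl, peak_amplitude_uv=amp, peak_latency_ms=lat)
    return replace(p,
                   p3cue=bump(p.p3cue, +1), p3go=bump(p.p3go, +1),
                   n2stop=bump(p.n2stop, -1), p3stop=bump(p.p3stop, +1))


def simulate_study(n_per_group: int = 30,
                   group_effects: dict[str, tuple[RaceModelParams, ErpTemplateParams]] | None = None,
                   seed: int = 0,
                   design: DesignParams | None = None,
                   between_subject_sd_ms: float = 25.0,
                   between_subject_sd_uv: float = 0.6,
                   with_eeg: bool = True) -> list[SimulatedSession]:
    """Simulate a two-group study (default 30 subjects per group).

    Per-subject parameters are drawn around the group-level means with the
    given between-subject SDs; each session's ``race_params`` /
    ``erp_params`` record the subject's own truth for recovery tests.
    ``with_eeg=False`` skips EEG synthesis (behavior-only studies).
    """
    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2")
    effects = group_effects or default_group_params()
    rng = np.random.default_rng(seed)
    sessions: list[SimulatedSession] = []
    for group, (race0, erp0) in effects.items():
        for i in range(n_per_group):
            race = _jitter_race(rng, race0, between_subject_sd_ms)
            erp = _jitter_erp(rng, erp0, between_subject_sd_uv)
            sub_seed = int(rng.integers(2 ** 31))
            sid = f"sub-{group}{i:02d}"
            if with_eeg:
                sess = simulate_session(design, race, erp, seed=sub_seed,
                                        subject_id=sid, group=group)
            else:
                srng = np.random.default_rng(sub_seed)
                schedule = generate_schedule(design, seed=int(srng.integers(2 ** 31)))
                behavior = simulate_behavior(schedule, race,
                                             seed=int(srng.integers(2 ** 31)))
                sess = SimulatedSession(
                    schedule=schedule, behavior=behavior,
                    eeg_uv=np.zeros((len(ALL_CHANNELS), 0)),
                    ch_names=ALL_CHANNELS, sfreq=SFREQ,
                    events=pd.DataFrame(), race_params=race, erp_params=erp,
                    subject_id=sid, group=group)
            sess.race_params = race
            sessions.append(sess)
    return sessions


def simulate_measures(n_per_group: int = 30,
                      group_effects: dict[str, tuple[RaceModelParams, ErpTemplateParams]] | None = None,
                      seed: int = 0,
                      conditions: tuple[str, ...] = ("reactive", "proactive"),
                      electrodes: dict[str, tuple[str, ...]] | None = None,
                      between_subject_sd_uv: float = 0.8,
                      measurement_sd_uv: float = 0.5,
                      latency_sd_ms: float = 15.0) -> pd.DataFrame:
    """Subject-level component-measure table drawn from the group model.

    Generates the tidy (subject, group, component, condition, direction,
    electrode, amplitude_uv, latency_ms) table directly — the quantity the
    group statistics operate on — without synthesizing raw EEG.  Amplitude
    = group template amplitude + subject offset + cell measurement noise;
    latency likewise around the template peak.  Used for statistical
    calibration and power studies where hundreds of replicate studies are
    needed.
    """
    effects = group_effects or default_group_params()
    electrodes = electrodes or {"P3cue": FRONTAL, "P3go": CENTRAL,
                                "N2stop": FRONTAL, "P3stop": CENTRAL}
    directions = {"P3cue": ("n/a",), "P3go": ("n/a",),
                  "N2stop": ("left", "right"), "P3stop": ("left", "right")}
    rng = np.random.default_rng(seed)
    rows = []
    for group, (_, erp0) in effects.items():
        for i in range(n_per_group):
            sid = f"sub-{group}{i:02d}"
            subj_off = rng.normal(0, between_subject_sd_uv)
            subj_lat = rng.normal(0, latency_sd_ms)
            for comp, chans in electrodes.items():
                tpl = erp0.component(comp)
                for condition in conditions:
                    for direction in directions[comp]:
                        for ch in chans:
                            amp = (tpl.peak_amplitude_uv + subj_off
                                   + rng.normal(0, measurement_sd_uv))
                            lat = (tpl.peak_latency_ms + subj_lat
                                   + rng.normal(0, latency_sd_ms / 2))
                            rows.append(dict(
                                subject=sid, group=group, component=comp,
                                condition=condition, direction=direction,
                                electrode=ch, amplitude_uv=amp,
                                latency_ms=lat))
    return pd.DataFrame(rows)
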