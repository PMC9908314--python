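"""Forward simulation of tilt-evoked GCaMP fluorescence.

The generative model has three stages:

1. **Waveform** — the signed platform angle over time (`tipm.protocols`).
2. **Drive** — the ΔF/F-equivalent neural drive: a *tonic* term proportional
   to the rectified roll angle (ipsilateral and contralateral gains, shaped by
   the neuron's hold decay class) plus a *phasic* delta at each rapid platform
   transition.
3. **Fluorescence** — the drive low-pass filtered by a causal, unit-area
   double-exponential indicator kernel (slow GCaMP6s-like kinetics), scaled
   onto a baseline fluorescence, resampled at the volumetric imaging rate, and
   corrupted with Gaussian measurement noise on the recorded samples.

With a unit-area kernel the steady-state ΔF/F during a long hold equals the
tonic drive exactly (gain x angle), while phasic deltas are normalized so the
rendered transient peaks at ``phasic_gain``.

Because the post-return readout window samples the indicator during its decay,
the *expected measured* peak is a deterministic, kernel-dependent fraction of
the hold steady state.  The experiment simulator therefore records per-cell
"implied" slopes and directionality — the values the noise-free forward model
yields through the same extraction windows — as the recoverable ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .neurons import NeuronGroundTruth, make_population
from .protocols import StimulusProtocol, generate_waveform

__all__ = [
    "SimulationConfig",
    "indicator_kernel",
    "kernel_peak",
    "simulate_drive",
    "render_fluorescence",
    "default_protocols",
    "simulate_experiment",
    "generate_frame_pair",
    "write_frame_pair",
    "config_from_yaml",
]

#: Tidy trace-table columns, one row per recorded volume.
TRACE_COLUMNS = [
    "fish_id", "cell_id", "session_id", "age_dpf", "trial_id", "repeat_id",
    "stim_kind", "stim_direction", "stim_magnitude_deg", "time_s", "F",
    "baseline_s", "hold_s", "response_s", "transition_ms", "hemisphere",
]

_EVENT_SPEED_THRESHOLD_DEG_S = 200.0


# ---------------------------------------------------------------------------
# indicator kernel
# ---------------------------------------------------------------------------

def kernel_peak(rise_tau_s: float, decay_tau_s: float) -> tuple[float, float]:
    """Analytic (time, value) of the unit-area double-exponential kernel peak.

    k(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / (tau_d - tau_r),  t >= 0.
    """
    tr, td = rise_tau_s, decay_tau_s
    t_star = tr * td / (td - tr) * np.log(td / tr)
    k_star = (np.exp(-t_star / td) - np.exp(-t_star / tr)) / (td - tr)
    return float(t_star), float(k_star)


def indicator_kernel(
    rise_tau_s: float, decay_tau_s: float, rate_hz: float
) -> np.ndarray:
    """Sampled causal double-exponential kernel, renormalized to unit area.

    The kernel is truncated where the decay envelope falls below 1e-5 of its
    peak and renormalized so that ``sum(kernel) / rate_hz == 1`` exactly; a
    sustained drive of level L then settles at ΔF/F = L.
    """
    if rise_tau_s <= 0 or decay_tau_s <= 0:
        raise ValueError("indicator time constants must be positive")
    if decay_tau_s <= rise_tau_s:
        raise ValueError("decay_tau_s must exceed rise_tau_s")
    t_max = decay_tau_s * np.log(1e5)
    t = np.arange(0.0, t_max, 1.0 / rate_hz)
    k = np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s)
    k /= k.sum() / rate_hz
    return k


# ---------------------------------------------------------------------------
# drive
# ---------------------------------------------------------------------------

def _tonic_target(
    t: np.ndarray, angle: np.ndarray, neuron: NeuronGroundTruth
) -> np.ndarray:
    """Tonic drive level (ΔF/F) from the signed angle, with hold-decay shaping."""
    tonic = (
        neuron.utricle_scale * neuron.tonic_gain_ipsi * np.maximum(angle, 0.0)
        + neuron.tonic_gain_contra * np.maximum(-angle, 0.0)
    )
    if neuron.decay_class == "fast_decay" and neuron.decay_rate > 0 and tonic.any():
        i_peak = int(np.argmax(tonic))
        ramp = neuron.decay_rate * np.maximum(t - t[i_peak], 0.0)
        tonic = np.maximum(tonic - ramp, 0.0)
    return tonic


def _detect_events(t: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Midpoint times of rapid platform transitions in a sampled trajectory."""
    if len(t) < 2:
        return np.empty(0)
    speed = np.abs(np.diff(angle)) / np.diff(t)
    fast = speed > _EVENT_SPEED_THRESHOLD_DEG_S
    events = []
    i = 0
    while i < len(fast):
        if fast[i]:
            j = i
            while j + 1 < len(fast) and fast[j + 1]:
                j += 1
            events.append(0.5 * (t[i] + t[j + 1]))
            i = j + 1
        i += 1
    return np.asarray(events)


def _inject_events(
    drive: np.ndarray, t: np.ndarray, event_times: np.ndarray, neuron: NeuronGroundTruth
) -> None:
    """Add phasic deltas in place; each rendered transient peaks at phasic_gain."""
    if neuron.phasic_gain <= 0 or len(event_times) == 0:
        return
    dt = t[1] - t[0]
    _, k_max = kernel_peak(neuron.rise_tau_s, neuron.decay_tau_s)
    area = neuron.phasic_gain / k_max
    idx = np.clip(np.rint(event_times / dt).astype(int), 0, len(drive) - 1)
    np.add.at(drive, idx, area / dt)


def simulate_drive(
    t: np.ndarray, angle: np.ndarray, neuron: NeuronGroundTruth
) -> np.ndarray:
    """Instantaneous drive (ΔF/F-equivalent) for a sampled trajectory.

    The tonic component is the rectified, gain-scaled angle (ipsilateral gain
    additionally scaled by ``utricle_scale``), shaped by the neuron's decay
    class over the hold.  Each rapid transition (angular speed above
    200 deg/s) contributes a delta whose convolution with the indicator
    kernel peaks at ``phasic_gain`` ΔF/F.
    """
    t = np.asarray(t, float)
    angle = np.asarray(angle, float)
    drive = _tonic_target(t, angle, neuron)
    _inject_events(drive, t, _detect_events(t, angle), neuron)
    return drive


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _convolve_drive(drive: np.ndarray, kernel: np.ndarray, rate_hz: float) -> np.ndarray:
    from scipy.signal import fftconvolve

    return fftconvolve(drive, kernel)[: len(drive)] / rate_hz


def _sample_times(total_s: float, sample_rate_hz: float) -> np.ndarray:
    n = int(round(total_s * sample_rate_hz))
    return np.arange(n) / sample_rate_hz


def render_fluorescence(
    t: np.ndarray,
    drive: np.ndarray,
    neuron: NeuronGroundTruth,
    *,
    sample_rate_hz: float = 2.2,
    rng: np.random.Generator | int | None = None,
    add_noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Render a drive time series into sampled raw fluorescence.

    F(t) = baseline_F * (1 + (drive * kernel)(t)) + N(0, noise_sd * baseline_F)
    with the noise drawn independently per *recorded* sample (volume).

    Returns ``(time_s, F)`` at the imaging rate; trace length is
    ``round(duration * sample_rate_hz)``.
    """
    t = np.asarray(t, float)
    drive = np.asarray(drive, float)
    if sample_rate_hz <= 0:
        raise ValueError("sample_rate_hz must be positive")
    dt = t[1] - t[0]
    rate = 1.0 / dt
    kernel = indicator_kernel(neuron.rise_tau_s, neuron.decay_tau_s, rate)
    dff = _convolve_drive(drive, kernel, rate)
    ts = _sample_times(t[-1] + dt, sample_rate_hz)
    idx = np.clip(np.rint(ts * rate).astype(int), 0, len(dff) - 1)
    F = neuron.baseline_F * (1.0 + dff[idx])
    if add_noise and neuron.noise_sd > 0:
        rng = np.random.default_rng(rng)
        F = F + rng.normal(0.0, neuron.noise_sd * neuron.baseline_F, len(F))
    return ts, F


# ---------------------------------------------------------------------------
# experiment-level simulation
# ---------------------------------------------------------------------------

def default_protocols(
    kind: str = "step",
    magnitudes: tuple[float, ...] = (10.0, 20.0, 30.0),
    directions: tuple[str, ...] = ("ipsi", "contra"),
    *,
    baseline_s: float = 6.0,
    hold_s: float | None = None,
    response_s: float = 5.0,
) -> list[StimulusProtocol]:
    """The standard stimulus battery: each magnitude in each direction."""
    protos = []
    for d in directions:
        for m in magnitudes:
            kwargs = dict(
                kind=kind, direction=d, magnitude_deg=float(m),
                baseline_s=baseline_s, response_s=response_s,
            )
            if hold_s is not None:
                kwargs["hold_s"] = hold_s
            elif kind == "impulse":
                from .protocols import default_impulse_hold_s

                kwargs["hold_s"] = default_impulse_hold_s(float(m))
            protos.append(StimulusProtocol(**kwargs))
    return protos


@dataclass
class SimulationConfig:
    """Everything needed to simulate one imaging session.

    ``seed`` fans out through `numpy.random.SeedSequence` spawn keys indexed
    by (cell, protocol, trial, repeat), so adding trials or cells never
    reshuffles the noise of earlier ones.  ``anesthetized=True`` forces all
    neural gains to zero (fluorescence = baseline + noise).
    ``mount_roll_jitter_deg`` is the SD of a per-session roll offset added to
    the whole trajectory (0 by default: a single mount has no remount
    variability).
    """

    protocols: list[StimulusProtocol]
    neurons: list[NeuronGroundTruth]
    sample_rate_hz: float = 2.2
    trials_per_magnitude: int = 3
    repeats_per_trial: int = 2
    seed: int = 0
    anesthetized: bool = False
    mount_roll_jitter_deg: float = 0.0
    fish_id: str = "fish01"
    session_id: str = "s01"
    age_dpf: int = 4
    render_rate_hz: float = 100.0
    waveform_rate_hz: float = 5000.0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.trials_per_magnitude < 1 or self.repeats_per_trial < 1:
            raise ValueError("trial and repeat counts must be >= 1")


def _trial_rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _window_mean(ts: np.ndarray, x: np.ndarray, start: float, stop: float) -> float:
    m = (ts >= start) & (ts < stop)
    return float(x[m].mean()) if m.any() else float("nan")


def _noise_free_peak(proto: StimulusProtocol, ts: np.ndarray, dff_s: np.ndarray) -> float:
    """Mean noise-free ΔF/F in the first second after the return to horizontal."""
    return _window_mean(ts, dff_s, proto.t_return, proto.t_return + 1.0)


def _implied_ground_truth(
    protos: list[StimulusProtocol], peaks: dict[int, float]
) -> dict:
    """Implied per-direction slopes and DI from noise-free measured peaks."""
    out: dict = {}
    for d in ("ipsi", "contra"):
        pts = [
            (p.magnitude_deg, peaks[i])
            for i, p in enumerate(protos)
            if p.direction == d and p.kind == "step"
        ]
        if len({m for m, _ in pts}) >= 2:
            x = np.array([m for m, _ in pts])
            y = np.array([v for _, v in pts])
            xc = x - x.mean()
            out[f"implied_slope_{d}"] = float((xc @ (y - y.mean())) / (xc @ xc))
    step_mags = [p.magnitude_deg for p in protos if p.kind == "step"]
    if step_mags:
        m_top = max(step_mags)
        r = {
            p.direction: peaks[i]
            for i, p in enumerate(protos)
            if p.kind == "step" and p.magnitude_deg == m_top
        }
        if "ipsi" in r and "contra" in r and (r["ipsi"] + r["contra"]) > 0:
            out["implied_di"] = float(
                (r["ipsi"] - r["contra"]) / (r["ipsi"] + r["contra"])
            )
    return out


def simulate_experiment(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a full session and return (tidy trace table, ground truth).

    The trace table has one row per recorded volume (columns
    ``TRACE_COLUMNS``); the ground-truth dict maps ``cell_id`` to the neuron's
    generative parameters plus the implied (noise-free, pipeline-measured)
    sensitivity slopes and directionality index.
    """
    cfg = config
    # per-session mount roll offset (degrees, world frame)
    if cfg.mount_roll_jitter_deg > 0:
        mount_offset = float(
            _trial_rng(cfg.seed, 999_983).normal(0.0, cfg.mount_roll_jitter_deg)
        )
    else:
        mount_offset = 0.0

    # Per-protocol precomputation: render-grid angle and sample times.
    step = int(round(cfg.waveform_rate_hz / cfg.render_rate_hz))
    proto_cache = []
    for proto in cfg.protocols:
        t_fine, a_fine = generate_waveform(proto, cfg.waveform_rate_hz)
        t_r, a_r = t_fine[::step], a_fine[::step]
        ts = _sample_times(proto.total_s, cfg.sample_rate_hz)
        idx = np.clip(np.rint(ts * cfg.render_rate_hz).astype(int), 0, len(t_r) - 1)
        proto_cache.append((proto, t_r, a_r, ts, idx))

    ts_chunks: list[np.ndarray] = []
    f_chunks: list[np.ndarray] = []
    meta_rows: list[tuple] = []  # one per trial-repeat sweep, with sample count
    ground_truth: dict[str, dict] = {}
    for ci, neuron in enumerate(cfg.neurons):
        if cfg.anesthetized:
            neuron_eff = dataclasses.replace(
                neuron, tonic_gain_ipsi=0.0, tonic_gain_contra=0.0, phasic_gain=0.0
            )
        else:
            neuron_eff = neuron
        rel_offset = mount_offset if neuron.hemisphere == "left" else -mount_offset
        kernel = indicator_kernel(
            neuron.rise_tau_s, neuron.decay_tau_s, cfg.render_rate_hz
        )
        nf_peaks: dict[int, float] = {}
        for pi, (proto, t_r, a_r, ts, idx) in enumerate(proto_cache):
            drive = _tonic_target(t_r, a_r + rel_offset, neuron_eff)
            _inject_events(drive, t_r, np.asarray(proto.event_times), neuron_eff)
            dff = _convolve_drive(drive, kernel, cfg.render_rate_hz)
            dff_s = dff[idx]
            nf_peaks[pi] = _noise_free_peak(proto, ts, dff_s)
            F_clean = neuron.baseline_F * (1.0 + dff_s)
            n = len(ts)
            for trial in range(cfg.trials_per_magnitude):
                for rep in range(cfg.repeats_per_trial):
                    rng = _trial_rng(cfg.seed, ci, pi, trial, rep)
                    if neuron.noise_sd > 0:
                        F = F_clean + rng.normal(
                            0.0, neuron.noise_sd * neuron.baseline_F, n
                        )
                    else:
                        F = F_clean.copy()
                    ts_chunks.append(ts)
                    f_chunks.append(F)
                    meta_rows.append(
                        (
                            n,
                            cfg.fish_id,
                            neuron.cell_id,
                            cfg.session_id,
                            cfg.age_dpf,
                            f"{proto.kind}_{proto.direction}"
                            f"_{proto.magnitude_deg:g}_t{trial}",
                            rep,
                            proto.kind,
                            proto.direction,
                            proto.magnitude_deg,
                            proto.baseline_s,
                            proto.hold_s,
                            proto.response_s,
                            proto.transition_ms,
                            neuron.hemisphere,
                        )
                    )
        gt = neuron.to_dict()
        gt.update(_implied_ground_truth(cfg.protocols, nf_peaks))
        gt["mount_roll_offset_deg"] = mount_offset
        ground_truth[neuron.cell_id] = gt

    counts = np.array([m[0] for m in meta_rows])
    scalar_cols = [
        "fish_id", "cell_id", "session_id", "age_dpf", "trial_id", "repeat_id",
        "stim_kind", "stim_direction", "stim_magnitude_deg",
        "baseline_s", "hold_s", "response_s", "transition_ms", "hemisphere",
    ]
    data = {
        col: np.repeat(np.array([m[i + 1] for m in meta_rows]), counts)
        for i, col in enumerate(scalar_cols)
    }
    data["time_s"] = np.concatenate(ts_chunks)
    data["F"] = np.concatenate(f_chunks)
    traces = pd.DataFrame(data)[TRACE_COLUMNS]
    return traces, ground_truth


# ---------------------------------------------------------------------------
# frame pairs for registration QC
# ---------------------------------------------------------------------------

def generate_frame_pair(
    shift_px: tuple[int, int],
    seed: int | None = None,
    *,
    size: int = 64,
    noise_sd: float = 0.0,
    structured: bool = True,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Two 2-D frames, the second translated by ``shift_px`` = (dx, dy).

    dx shifts along axis 1 (x), dy along axis 0 (y): feature at (r, c) in the
    first frame appears at (r + dy, c + dx) in the second.  Frames are cropped
    from one larger smooth random field, so the translation is exact with no
    wrap-around.  ``structured=False`` yields two independent pure-noise
    frames (no common structure).  Returns (frame_pre, frame_post, info) with
    the ground-truth shift in ``info``.
    """
    from scipy.ndimage import gaussian_filter

    dx, dy = int(shift_px[0]), int(shift_px[1])
    if abs(dx) >= size or abs(dy) >= size:
        raise ValueError("shift must be smaller than the frame size")
    rng = np.random.default_rng(seed)
    pad = max(abs(dx), abs(dy)) + 4
    if structured:
        base = gaussian_filter(rng.normal(size=(size + 2 * pad,) * 2), sigma=3.0)
        base = (base - base.mean()) / base.std()
        pre = base[pad : pad + size, pad : pad + size].copy()
        post = base[pad - dy : pad - dy + size, pad - dx : pad - dx + size].copy()
    else:
        pre = rng.normal(size=(size, size))
        post = rng.normal(size=(size, size))
    if noise_sd > 0:
        pre = pre + rng.normal(0.0, noise_sd, pre.shape)
        post = post + rng.normal(0.0, noise_sd, post.shape)
    info = {"dx_px": dx, "dy_px": dy, "size": size, "noise_sd": noise_sd,
            "structured": structured}
    return pre.astype(np.float32), post.astype(np.float32), info


def write_frame_pair(
    path: str | Path, pre: np.ndarray, post: np.ndarray, info: dict | None = None
) -> None:
    """Write a frame pair as a 2-page TIFF, with a JSON sidecar if info given."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.stack([pre, post]))
    if info is not None:
        path.with_suffix(".json").write_text(json.dumps(info, indent=2))


# ---------------------------------------------------------------------------
# YAML configuration
# ---------------------------------------------------------------------------

def config_from_yaml(path_or_dict: str | Path | dict) -> SimulationConfig:
    """Build a `SimulationConfig` from a YAML file (or parsed dict).

    Schema::

        seed: 7
        n_cells: 70
        sample_rate_hz: 2.2
        trials_per_magnitude: 3
        repeats_per_trial: 2
        anesthetized: false
        mount_roll_jitter_deg: 0.0
        fish_id: fish01
        session_id: s01
        age_dpf: 4
        stimuli: {kind: step, magnitudes: [10, 20, 30],
                  directions: [ipsi, contra], baseline_s: 6.0,
                  hold_s: 15.0, response_s: 5.0}
        population: {...}   # keyword args of tipm.neurons.make_population
    """
    if isinstance(path_or_dict, dict):
        raw = dict(path_or_dict)
    else:
        raw = yaml.safe_load(Path(path_or_dict).read_text())
    stim = dict(raw.pop("stimuli", {}))
    kind = stim.pop("kind", "step")
    magnitudes = tuple(stim.pop("magnitudes", (10.0, 20.0, 30.0)))
    directions = tuple(stim.pop("directions", ("ipsi", "contra")))
    protocols = default_protocols(kind, magnitudes, directions, **stim)
    pop = dict(raw.pop("population", {}))
    for key in ("gain_ipsi_range", "gain_contra_range", "phasic_gain_range",
                "decay_rate_range"):
        if key in pop:
            pop[key] = tuple(pop[key])
    n_cells = int(raw.pop("n_cells", 70))
    seed = int(raw.get("seed", 0))
    neurons = make_population(n_cells, np.random.default_rng(seed + 1), **pop)
    return SimulationConfig(protocols=protocols, neurons=neurons, **raw)
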