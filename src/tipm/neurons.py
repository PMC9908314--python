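"""Ground-truth neuron parameters for the forward simulator.

Each simulated vestibulospinal neuron is described by tonic gains (steady-state
ΔF/F per degree of ipsilateral / contralateral roll), a phasic gain (peak ΔF/F
of the transient evoked by each rapid platform transition), indicator kinetics,
an eccentric-hold decay class, measurement noise, and an anatomical position
relative to the Mauthner lateral dendrite tip of its hemisphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["NeuronGroundTruth", "make_population"]


@dataclass(frozen=True)
class NeuronGroundTruth:
    """Forward-model parameters for one simulated neuron.

    ``tonic_gain_ipsi``/``tonic_gain_contra`` are ΔF/F per degree of roll
    toward/away from the neuron's hemisphere.  ``utricle_scale`` multiplies
    the ipsilateral tonic gain only (0 models loss of the utricular otolith,
    which abolishes static-tilt drive but leaves contralateral and phasic
    drive intact).  ``decay_class`` shapes the tonic drive over a long hold:
    ``plateau`` holds the steady state; ``fast_decay`` declines linearly from
    its peak at ``decay_rate`` ΔF/F per second (floored at 0).
    """

    cell_id: str
    hemisphere: str = "left"
    tonic_gain_ipsi: float = 0.07
    tonic_gain_contra: float = 0.02
    phasic_gain: float = 0.25
    decay_class: str = "plateau"
    decay_rate: float = 0.0
    rise_tau_s: float = 0.18
    decay_tau_s: float = 1.8
    noise_sd: float = 0.5
    baseline_F: float = 300.0
    utricle_scale: float = 1.0
    position_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError("hemisphere must be 'left' or 'right'")
        if min(self.tonic_gain_ipsi, self.tonic_gain_contra, self.phasic_gain) < 0:
            raise ValueError("gains must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_F <= 0:
            raise ValueError("baseline_F must be > 0")
        if not 0.0 <= self.utricle_scale <= 1.0:
            raise ValueError("utricle_scale must lie in [0, 1]")
        if self.decay_class not in ("fast_decay", "plateau"):
            raise ValueError("decay_class must be 'fast_decay' or 'plateau'")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ValueError("indicator time constants must be positive")
        if self.decay_tau_s <= self.rise_tau_s:
            raise ValueError("decay_tau_s must exceed rise_tau_s")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["position_um"] = list(self.position_um)
        return d


def make_population(
    n_cells: int,
    rng: np.random.Generator | int | None = None,
    *,
    gain_ipsi_range: tuple[float, float] = (0.02, 0.12),
    gain_contra_range: tuple[float, float] = (0.0, 0.04),
    phasic_gain_range: tuple[float, float] = (0.05, 0.45),
    fast_decay_fraction: float = 0.5,
    decay_rate_range: tuple[float, float] = (0.03, 0.15),
    noise_sd: float = 0.5,
    utricle_scale: float = 1.0,
    decay_class: str | None = None,
    impulse_topography: bool = False,
    cell_prefix: str = "cell",
) -> list[NeuronGroundTruth]:
    """Draw a heterogeneous population of ground-truth neurons.

    Default ranges centre the population on the field's typical values: mean
    ipsilateral tonic gain 0.07 ΔF/F per degree, contralateral 0.02, phasic
    transients of a few tenths of a ΔF/F, and a mix of plateau and
    fast-decay hold dynamics.

    Parameters
    ----------
    decay_class : optional
        Force every cell to this decay class (overrides ``fast_decay_fraction``).
    impulse_topography : bool
        If True, cells with above-median phasic gain are placed more ventrally
        (dorsoventral z ~ N(-3.6, 7.0) µm) than the rest (z ~ N(2.2, 11.0) µm),
        emulating the ventrolateral bias of impulse-responsive somata.
    """
    rng = np.random.default_rng(rng)
    gi = rng.uniform(*gain_ipsi_range, n_cells)
    gc = rng.uniform(*gain_contra_range, n_cells)
    pg = rng.uniform(*phasic_gain_range, n_cells)
    baseline = rng.uniform(100.0, 1000.0, n_cells)
    hemi = rng.choice(["left", "right"], n_cells)
    if decay_class is None:
        fast = rng.random(n_cells) < fast_decay_fraction
    else:
        fast = np.full(n_cells, decay_class == "fast_decay")
    rate = np.where(fast, rng.uniform(*decay_rate_range, n_cells), 0.0)

    x = rng.uniform(5.0, 40.0, n_cells)
    y = rng.uniform(-20.0, 20.0, n_cells)
    if impulse_topography:
        ventral = pg > np.median(pg)
        z = np.where(ventral, rng.normal(-3.6, 7.0, n_cells), rng.normal(2.2, 11.0, n_cells))
    else:
        z = rng.normal(0.0, 10.0, n_cells)

    width = int(np.ceil(np.log10(max(n_cells, 2))))
    return [
        NeuronGroundTruth(
            cell_id=f"{cell_prefix}{i:0{width}d}",
            hemisphere=str(hemi[i]),
            tonic_gain_ipsi=float(gi[i]),
            tonic_gain_contra=float(gc[i]),
            phasic_gain=float(pg[i]),
            decay_class="fast_decay" if fast[i] else "plateau",
            decay_rate=float(rate[i]),
            noise_sd=float(noise_sd),
            baseline_F=float(baseline[i]),
            utricle_scale=float(utricle_scale),
            position_um=(float(x[i]), float(y[i]), float(z[i])),
        )
        for i in range(n_cells)
    ]
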