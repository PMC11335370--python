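"""Synthetic SILK-style MRM cohorts with the noise structure the models assume.

Emulates the study design of an intravenous 13C6-Leu infusion experiment:
9 h infusion, sampling roughly every 3 h (to ~36 h for plasma, ~24 h for
CSF), duplicate injections, intensity-dependent measurement noise and an
additive per-patient vertical shift of the observed ratios.

The generator inverts the population model: per-patient log-parameters
theta_k are drawn from N2(mu_theta, Omega), shifts s_k from N(0, shift_sd^2),
and each RIA from N(beta_k(t) - s_k, sigma^2 / w) where the weight w is
proportional to the synthetic heavy-channel intensity PH.  PH is modeled
as proportional to beta(t) plus a floor, so early time points carry low
weight — the rationale for PH-proportional weighting in the fitting
stages.  Light/heavy intensity pairs are reconstructed so that
PH/(PL+PH) reproduces the drawn ratio exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bayes_population import PatientData
from .kinetics import TracerProtocol, beta_values
from .qnb import RIAObservation

__all__ = ["SimulationScenario", "simulate_patient", "simulate_cohort",
           "cohort_to_frame", "PRESETS", "scenario_from_preset"]


@dataclass(frozen=True)
class SimulationScenario:
    """Ground-truth population and acquisition design for one simulation."""

    n_patients: int = 7
    mu_theta: np.ndarray = field(default_factory=lambda: np.log([0.05, 0.1]))
    omega: np.ndarray = field(default_factory=lambda: np.array([[0.04, 0.012],
                                                                [0.012, 0.04]]))
    shift_sd: float = 0.005
    noise_sd: float = 0.01
    t_start: float = 0.0
    t_end: float = 36.0
    t_spacing: float = 3.0
    duplicates: int = 2
    ph_scale: float = 1e5
    ph_floor: float = 0.02
    outlier_rate: float = 0.0
    infusion_end: float = 9.0
    aberrant_patient: bool = False
    aberrant_sds: float = 4.0
    protein_id: str = "SYN1"
    peptide_id: str = "PEP1"

    def __post_init__(self) -> None:
        om = np.asarray(self.omega, dtype=float)
        if om.shape != (2, 2) or not np.allclose(om, om.T):
            raise ValueError("omega must be symmetric 2x2")
        if np.any(np.linalg.eigvalsh(om) < -1e-12):
            raise ValueError("omega must be positive semi-definite")
        if not (0 <= self.t_start < self.t_end <= 36.0):
            raise ValueError("schedule must lie within [0, 36] h")
        if self.duplicates < 1:
            raise ValueError("duplicates must be >= 1")

    @property
    def schedule(self) -> np.ndarray:
        return np.arange(self.t_start, self.t_end + 1e-9, self.t_spacing)

    @property
    def protocol(self) -> TracerProtocol:
        return TracerProtocol(infusion_end=self.infusion_end)


PRESETS = {
    # moderate inter-individual variability, sampling to 36 h
    "plasma-like": SimulationScenario(),
    # noisier, wider population spread, faster turnover, sampling to 24 h
    "csf-like": SimulationScenario(
        mu_theta=np.log([0.08, 0.25]),
        omega=np.array([[0.25, 0.1], [0.1, 0.25]]),
        shift_sd=0.01, noise_sd=0.02, t_end=24.0, n_patients=4,
    ),
    # csf-like plus one patient forced far from the population mean,
    # mimicking a pathological cohort member
    "csf-aberrant": SimulationScenario(
        mu_theta=np.log([0.08, 0.25]),
        omega=np.array([[0.25, 0.1], [0.1, 0.25]]),
        shift_sd=0.01, noise_sd=0.02, t_end=24.0, n_patients=4,
        aberrant_patient=True,
    ),
}


def scenario_from_preset(preset: str, **overrides) -> SimulationScenario:
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[preset], **overrides)


def simulate_patient(theta_k, s_k, scenario: SimulationScenario,
                     rng: np.random.Generator,
                     patient_id: str = "P1") -> list[RIAObservation]:
    """Simulate one patient's duplicate RIA series under the noise model."""
    llam, lkc = float(theta_k[0]), float(theta_k[1])
    times = np.repeat(scenario.schedule, scenario.duplicates)
    reps = np.tile(np.arange(1, scenario.duplicates + 1), scenario.schedule.size)
    beta = beta_values(llam, lkc, times, scenario.protocol)
    ph = scenario.ph_scale * (beta + scenario.ph_floor)
    w = ph / ph.mean()
    ria = rng.normal(beta - s_k, scenario.noise_sd / np.sqrt(w))
    if scenario.outlier_rate > 0:
        hit = rng.random(times.size) < scenario.outlier_rate
        ria[hit] = rng.uniform(0.0, 1.0, size=hit.sum())
    # ratios are physical only in [0,1]; clip rare negatives (mostly t=0)
    ria = np.clip(ria, 0.0, 1.0)
    obs = []
    for t, rep, phi, ri in zip(times, reps, ph, ria):
        if ri >= 1.0:
            pl_i, ph_i = 0.0, phi
        elif ri <= 0.0:
            pl_i, ph_i = phi, 0.0
            ri = 0.0
        else:
            ph_i = phi
            pl_i = phi * (1.0 - ri) / ri
        obs.append(RIAObservation(
            patient_id=patient_id, protein_id=scenario.protein_id,
            peptide_id=scenario.peptide_id, time=float(t), pl=pl_i, ph=ph_i,
            replicate=int(rep), ria=float(ri),
        ))
    return obs


def simulate_cohort(scenario: SimulationScenario, seed: int | None = None):
    """Simulate a cohort; returns (patients, truth).

    ``patients`` is a list of :class:`PatientData` (time-0 rows excluded,
    weights mean-1 normalized, per the always-outlier rule for t=0);
    ``truth`` records theta_k, s_k and the generating (mu_theta, Omega).
    The ``aberrant_patient`` flag forces the last patient's theta at
    ``aberrant_sds`` population standard deviations from the mean.
    """
    rng = np.random.default_rng(seed)
    om = np.asarray(scenario.omega, dtype=float)
    jitter = om + 1e-12 * np.eye(2)
    theta = rng.multivariate_normal(scenario.mu_theta, jitter,
                                    size=scenario.n_patients, method="cholesky")
    if scenario.aberrant_patient:
        sds = np.sqrt(np.diag(om))
        theta[-1] = scenario.mu_theta + scenario.aberrant_sds * sds * np.array([1.0, -1.0])
    shifts = rng.normal(0.0, scenario.shift_sd, size=scenario.n_patients)
    patients, all_obs, truth_rows = [], [], []
    for k in range(scenario.n_patients):
        pid = f"Pat{k + 1}"
        obs = simulate_patient(theta[k], shifts[k], scenario, rng, patient_id=pid)
        all_obs.append(obs)
        keep = [o for o in obs if o.time > 0 and o.ph > 0]
        t = np.array([o.time for o in keep])
        y = np.array([o.ria for o in keep])
        w = np.array([o.ph for o in keep])
        patients.append(PatientData(patient_id=pid, times=t, ria=y, weights=w))
        truth_rows.append({"patient_id": pid, "log_lam": theta[k, 0],
                           "log_kc": theta[k, 1], "shift": shifts[k]})
    truth = {
        "mu_theta": scenario.mu_theta.tolist(),
        "omega": om.tolist(),
        "noise_sd": scenario.noise_sd,
        "patients": truth_rows,
    }
    return patients, {"truth": truth, "observations": all_obs}


def cohort_to_frame(extras) -> pd.DataFrame:
    """Flatten simulated observations into the long-format cohort table."""
    rows = []
    for obs in extras["observations"]:
        for o in obs:
            rows.append({
                "patient": o.patient_id, "protein": o.protein_id,
                "peptide": o.peptide_id, "charge": 2,
                "replicate": o.replicate, "time_h": o.time,
                "pl": o.pl, "ph": o.ph,
            })
    return pd.DataFrame(rows)
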