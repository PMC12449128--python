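"""Synthetic 4-D BOLD data with belief-coupled across-trial variability.

The generator produces, for each scanner run of a task session, a voxel
time series in which every sample event elicits a response of random
amplitude. In designated *effect* voxels the across-trial dispersion of
those amplitudes tracks the observer's belief uncertainty: the amplitude
SD for trial t, sample period s is

    sd(t, s) = base + gain * Var_posterior(t, s) / Var_flat_prior,

where Var_posterior is the posterior variance of the agent's belief after
sample s and Var_flat_prior = 1/12 is the variance of the flat Beta(1, 1)
prior (one global normalizer for all subjects, so that agents who reduce
uncertainty more show steeper amplitude-SD compression in absolute
terms). *Null* voxels receive a
constant amplitude SD. Amplitudes are convolved with the canonical HRF;
white Gaussian scanner noise and optional low-frequency drift are added.

An explicit per-period SD schedule can be supplied instead of the belief
coupling, which gives the ground truth for recovery checks of the
downstream LS-S / SD_BOLD pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import nibabel as nib

from .glm import _event_regressors
from .task import TrialSequence, block_events

__all__ = [
    "VoxelLayout",
    "BoldRun",
    "NoiseSpec",
    "make_layout",
    "generate_subject_bold",
    "write_bids_like",
    "FLAT_PRIOR_VAR",
]

FLAT_PRIOR_VAR = 1.0 / 12.0
DEFAULT_TR = 0.645


@dataclass
class NoiseSpec:
    """Scanner noise: white Gaussian SD, optional sinusoidal drift."""

    white_sd: float = 0.2
    drift_amplitude: float = 0.0
    drift_period_s: float = 128.0
    ar_coef: float = 0.0


@dataclass
class VoxelLayout:
    """Voxel grid with an in-brain mask and effect/null labels.

    ``labels`` is defined over masked voxels (1 = effect, 0 = null); the
    effect voxels form a contiguous block so that cluster thresholding is
    meaningful downstream.
    """

    shape: tuple
    mask: np.ndarray  # bool, full grid
    labels: np.ndarray  # int, per masked voxel (flattened mask order)
    gain: float = 1.0
    base: float = 0.05
    null_sd: float = 0.2
    #: amplitude SD of estimation/gambling-phase responses (all voxels)
    nuisance_sd: float = 0.0
    mean_amplitude: float = 1.0

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def effect_index(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 1)

    @property
    def null_index(self) -> np.ndarray:
        return np.flatnonzero(self.labels == 0)

    def unmask(self, values: np.ndarray) -> np.ndarray:
        """Scatter a per-masked-voxel vector back into the 3-D grid."""
        vol = np.zeros(self.shape, dtype=float)
        vol[self.mask] = values
        return vol


def make_layout(
    shape=(12, 12, 12),
    mask_size=(6, 6, 6),
    effect_size=(6, 3, 6),
    gain: float = 1.0,
    base: float = 0.05,
    null_sd: float = 0.2,
) -> VoxelLayout:
    """Desk-scale geometry: a ~200-voxel box mask with a contiguous effect block."""
    mask = np.zeros(shape, dtype=bool)
    off = [(s - m) // 2 for s, m in zip(shape, mask_size)]
    mask[
        off[0] : off[0] + mask_size[0],
        off[1] : off[1] + mask_size[1],
        off[2] : off[2] + mask_size[2],
    ] = True
    effect_vol = np.zeros(shape, dtype=bool)
    effect_vol[
        off[0] : off[0] + effect_size[0],
        off[1] : off[1] + effect_size[1],
        off[2] : off[2] + effect_size[2],
    ] = True
    labels = effect_vol[mask].astype(int)
    return VoxelLayout(
        shape=shape, mask=mask, labels=labels, gain=gain, base=base, null_sd=null_sd
    )


@dataclass
class BoldRun:
    """One scanner run: time x voxel data plus its event table."""

    data: np.ndarray  # (n_scans, n_voxels) over masked voxels
    tr: float
    events: pd.DataFrame
    run_id: int
    amplitudes: np.ndarray | None = None  # ground-truth event amplitudes

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def _amplitude_sds(trajectory, layout, amp_sd_by_period):
    """Per-sample-period amplitude SD for one trial (effect voxels)."""
    if amp_sd_by_period is not None:
        return np.asarray(amp_sd_by_period, float)
    post_var = np.array([state.variance for state in trajectory[1:]])
    return layout.base + layout.gain * post_var / FLAT_PRIOR_VAR


def generate_subject_bold(
    sequence: TrialSequence,
    trajectories,
    layout: VoxelLayout,
    noise: NoiseSpec | None = None,
    rng: np.random.Generator | None = None,
    tr: float = DEFAULT_TR,
    amp_sd_by_period=None,
    hrf_tail_s: float = 25.0,
    sample_events_only: bool = False,
) -> list[BoldRun]:
    """Simulate one run per task block for a subject.

    Parameters
    ----------
    trajectories : list
        Per-trial belief-state lists (prior + one state per sample), aligned
        with ``sequence.trials``; may be None when ``amp_sd_by_period`` is
        given.
    amp_sd_by_period : array-like of 5 floats, optional
        Explicit amplitude-SD schedule for effect voxels, overriding the
        belief coupling (ground-truth mode for pipeline recovery checks).
    sample_events_only : bool
        Drop estimation/gambling events from the design, isolating the
        sampling phase (used for recovery calibration where cross-event
        leakage from long nuisance events would confound the schedule).
    """
    noise = noise or NoiseSpec()
    rng = rng or np.random.default_rng()
    if amp_sd_by_period is None:
        if trajectories is None or len(trajectories) != len(sequence.trials):
            raise ValueError("trajectories misaligned with sequence trials")
        traj_by_trial = {
            t.trial_id: traj for t, traj in zip(sequence.trials, trajectories)
        }
    runs = []
    n_vox = layout.n_voxels
    eff, nul = layout.effect_index, layout.null_index
    for block_id in range(sequence.n_blocks):
        events = block_events(sequence, block_id)
        if sample_events_only:
            events = (
                events[events["trial_type"].str.startswith("sample_")]
                .reset_index(drop=True)
            )
        run_end = float(events["onset"].max() + events["duration"].max()) + hrf_tail_s
        n_scans = int(np.ceil(run_end / tr))
        amplitudes = np.zeros((len(events), n_vox))
        sd_cache: dict = {}
        for row, ev in events.iterrows():
            if ev["trial_type"].startswith("sample_"):
                period = int(ev["trial_type"].split("_")[1]) - 1
                tid = int(ev["trial_id"])
                if tid not in sd_cache:
                    traj = None if amp_sd_by_period is not None else traj_by_trial[tid]
                    sd_cache[tid] = _amplitude_sds(traj, layout, amp_sd_by_period)
                sds = sd_cache[tid]
                amplitudes[row, eff] = rng.normal(
                    layout.mean_amplitude, sds[period], size=eff.size
                )
                amplitudes[row, nul] = rng.normal(
                    layout.mean_amplitude, layout.null_sd, size=nul.size
                )
            elif layout.nuisance_sd > 0:
                amplitudes[row] = rng.normal(
                    layout.mean_amplitude, layout.nuisance_sd, size=n_vox
                )
            else:
                # estimation / gambling phases evoke a fixed-amplitude response
                amplitudes[row] = layout.mean_amplitude
        design = _event_regressors(
            events["onset"], events["duration"], np.ones(len(events)), tr, n_scans
        )[:, :, 0]  # canonical response only
        data = design @ amplitudes
        if noise.white_sd > 0:
            eps = rng.normal(0.0, noise.white_sd, size=data.shape)
            if noise.ar_coef > 0:
                for i in range(1, eps.shape[0]):
                    eps[i] += noise.ar_coef * eps[i - 1]
            data += eps
        if noise.drift_amplitude > 0:
            t = np.arange(n_scans) * tr
            data += noise.drift_amplitude * np.sin(
                2 * np.pi * t / noise.drift_period_s
            )[:, None]
        runs.append(
            BoldRun(
                data=data, tr=tr, events=events, run_id=block_id, amplitudes=amplitudes
            )
        )
    return runs


def write_bids_like(runs, layout: VoxelLayout, out_dir, subject: str = "sub-01") -> dict:
    """Write runs as NIfTI-1 4-D volumes with BIDS-style events TSVs.

    Also writes the mask, the effect/null label volume and a ground-truth
    JSON (coupling parameters and per-run shapes). Returns the paths.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])  # RAS+, 3 mm isotropic
    paths = {"bold": [], "events": []}
    for run in runs:
        vol4d = np.zeros(layout.shape + (run.n_scans,), dtype=np.float32)
        vol4d[layout.mask] = run.data.T
        img = nib.Nifti1Image(vol4d, affine)
        img.header.set_zooms((3.0, 3.0, 3.0, run.tr))
        bold_path = out / f"{subject}_run-{run.run_id + 1}_bold.nii"
        nib.save(img, bold_path)
        ev_path = out / f"{subject}_run-{run.run_id + 1}_events.tsv"
        run.events.to_csv(ev_path, sep="\t", index=False)
        paths["bold"].append(str(bold_path))
        paths["events"].append(str(ev_path))
    mask_path = out / f"{subject}_mask.nii"
    nib.save(nib.Nifti1Image(layout.mask.astype(np.uint8), affine), mask_path)
    labels_path = out / f"{subject}_labels.nii"
    nib.save(
        nib.Nifti1Image(layout.unmask(layout.labels).astype(np.uint8), affine),
        labels_path,
    )
    truth = {
        "schema_version": 1,
        "gain": layout.gain,
        "base": layout.base,
        "null_sd": layout.null_sd,
        "mean_amplitude": layout.mean_amplitude,
        "tr": runs[0].tr if runs else None,
        "n_scans": [run.n_scans for run in runs],
    }
    truth_path = out / f"{subject}_ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    paths.update({"mask": str(mask_path), "labels": str(labels_path), "truth": str(truth_path)})
    return paths
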