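"""Shared simulation helpers for the test suite.

Small, fast study conditions: a 64^3 / 1.5 mm truth phantom sampled by a
2 mm cones acquisition over a 96 mm field of view, reconstructed on a 48^3
grid.  These sizes keep an end-to-end simulate -> reconstruct -> quantify
run to a few seconds while preserving the truth-vs-acquisition resolution
split of the full-size default phantom.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np

from naear import (
    PhantomSpec,
    SequenceParams,
    build_phantom,
    make_phase_cycles,
    make_trajectory,
    sample_kspace,
)
from naear.phantom import B0Params, PhantomSpec, PhantomVolume
from naear.pipeline import identity_transform
from naear.recon import ReconConfig, rss_composite, combine_fstates, reconstruct_cycle
from naear.registration import transfer_masks

SIM_PARAMS = SequenceParams(fov=96.0, resolution=2.0)
SIM_OFFSETS = (-60.0, 0.0, 60.0)


def sim_phantom_spec(left_fraction: float, right_fraction: float = 0.2, seed: int = 0):
    return PhantomSpec(
        grid_shape=(64, 64, 64),
        voxel_size=1.5,
        hydrops_fraction=(left_fraction, right_fraction),
        noise_seed=seed,
    )


@lru_cache(maxsize=1)
def sim_trajectory():
    return make_trajectory(
        SIM_PARAMS, "cones", n_readouts=1000, samples_per_readout=40
    )


def simulate_composites(
    phantom: PhantomVolume, noise_sd: float, seed: int, offsets=SIM_OFFSETS
):
    """Forward-simulate and reconstruct the RSS composite per sweep offset."""
    cycles = make_phase_cycles(SIM_PARAMS.n_phase_cycles)
    traj = sim_trajectory()
    kspace = sample_kspace(
        phantom, traj, SIM_PARAMS, cycles, noise_sd=noise_sd, seed=seed
    )
    cfg = ReconConfig(offsets=tuple(offsets))
    frames = []
    for off in offsets:
        imgs = [
            reconstruct_cycle(kspace, ic, off, cfg) for ic in range(len(cycles))
        ]
        frames.append(rss_composite(combine_fstates(imgs, cycles)))
    return np.stack(frames, axis=3), cfg


def recon_affine(grid=(48, 48, 48), voxel=2.0):
    aff = np.diag([voxel, voxel, voxel, 1.0])
    for i, n in enumerate(grid):
        aff[i, 3] = -(n // 2) * voxel
    return aff


def masks_on_recon_grid(phantom: PhantomVolume, grid=(48, 48, 48)):
    masks = {
        f"{s}_{d}": phantom.mask(s, d)
        for s in ("inner_ear", "iam_lateral")
        for d in ("left", "right")
    }
    out, _ = transfer_masks(
        masks, identity_transform(), phantom.affine, grid, recon_affine(grid)
    )
    return out


def inner_ear_medians(composite_stack: np.ndarray, masks) -> dict[str, float]:
    """Median composite NaSI per side, on the best (max-median) sweep frame."""
    out = {}
    for side in ("left", "right"):
        m = masks[f"inner_ear_{side}"]
        per_frame = [
            float(np.median(composite_stack[..., i][m]))
            for i in range(composite_stack.shape[3])
        ]
        out[side] = max(per_frame)
    return out


def banding_slab_phantom(seed: int, n: int = 32, voxel: float = 2.0) -> PhantomVolume:
    """Homogeneous fluid slab with a linear off-resonance gradient along y,
    spanning several bSSFP band periods -- bands appear as dark stripes."""
    shape = (n, n, n)
    conc = np.zeros(shape)
    lab = np.zeros(shape, np.int8)
    sl = (slice(n // 5, n - n // 5), slice(n // 5, n - n // 5),
          slice(n // 3, n - n // 3))
    conc[sl] = 145.0
    lab[sl] = 3
    off = np.broadcast_to(np.linspace(-150.0, 150.0, n)[None, :, None], shape).copy()
    rng = np.random.default_rng(seed)
    off = off + rng.normal(scale=3.0, size=shape)
    aff = np.diag([voxel, voxel, voxel, 1.0])
    aff[:3, 3] = -(n // 2) * voxel
    spec = PhantomSpec(grid_shape=shape, voxel_size=voxel, ear_offset=10.0,
                       noise_seed=seed)
    return PhantomVolume(
        concentration_map=conc,
        t1_map=np.full(shape, 60.0),
        t2_map=np.full(shape, 55.0),
        t2star_map=np.full(shape, 50.0),
        offres_map=off,
        label_map=lab,
        affine=aff,
        spec=spec,
    )


@lru_cache(maxsize=1)
def calibrated_noise_sd(target_snr: float = 5.0) -> float:
    """Noise level giving ROI SNR ~= target for the simulation conditions.

    SNR is defined as the noise-free normal-ear inner-ear median composite
    divided by the ROI mean of a noise-only composite at the same noise
    level (the composite of pure noise scales linearly with the noise SD).
    """
    phantom = build_phantom(sim_phantom_spec(0.9, 0.2, seed=0))
    masks = masks_on_recon_grid(phantom)
    clean, _ = simulate_composites(phantom, noise_sd=0.0, seed=0, offsets=(0.0,))
    signal = float(np.median(clean[..., 0][masks["inner_ear_right"]]))

    empty = dataclasses.replace(
        sim_phantom_spec(0.0, 0.0, seed=0),
        b0_params=B0Params(amplitude_hz=0.0, boundary_amplitude_hz=0.0),
    )
    blank = build_phantom(empty)
    blank.concentration_map[:] = 0.0
    noise_only, _ = simulate_composites(blank, noise_sd=1.0, seed=1, offsets=(0.0,))
    floor_per_unit_sd = float(np.mean(noise_only[..., 0][masks["inner_ear_right"]]))
    return signal / (target_snr * floor_per_unit_sd)
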