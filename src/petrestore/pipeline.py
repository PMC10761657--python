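"""End-to-end orchestration: simulate -> train -> denoise -> evaluate.

These functions tie the phantom simulator, slab handling, networks and
metrics together.  They back both the command-line interface and the
package's own validation experiments.  The "desk" experiment is a scaled
configuration of the full protocol -- small in-plane grids, tens of phantoms
and tens of epochs instead of 256 x 256 clinical volumes over 400 epochs --
chosen so the whole simulate/train/evaluate cycle runs on a single CPU in
minutes while preserving every structural element (multi-duration training,
CT fusion, slab tiling, normalization transfer).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import NetworkConfig, RestorationNet, build_network
from .phantom import (AcquisitionModel, CTVolume, PETVolume,
                      build_duration_series, generate_phantom,
                      random_phantom_spec)
from .training import LossConfig, TrainConfig, train
from .volio import (NormalizationConstants, S_DEFAULT, extract_slabs,
                    fit_normalization, normalize, denormalize, reassemble)

__all__ = [
    "DeskProfile",
    "simulate_cases",
    "build_slab_pairs",
    "denoise_volume",
    "run_desk_experiment",
]


@dataclass(frozen=True)
class DeskProfile:
    """Scaled experiment profile for single-CPU runs.

    The full-scale profile mirrors the clinical protocol (256 x 256 x 5
    slabs, 400 epochs); the desk defaults below keep the same pipeline at
    sizes a CPU handles in minutes.
    """
    grid_shape: tuple[int, int, int] = (32, 32, 5)
    n_train_phantoms: int = 24
    n_val_phantoms: int = 6
    epochs: int = 40
    base_channels: int = 8
    n_scales: int = 2
    n_res_blocks: int = 1
    n_res_blocks_decoder: int = 1
    train_stride: int = 2
    seed: int = 0

    def network_config(self, use_ct_branch: bool) -> NetworkConfig:
        return NetworkConfig(base_channels=self.base_channels,
                             n_scales=self.n_scales,
                             n_res_blocks=self.n_res_blocks,
                             n_res_blocks_decoder=self.n_res_blocks_decoder,
                             use_ct_branch=use_ct_branch)

    @classmethod
    def full_scale(cls) -> "DeskProfile":
        """The clinical-scale profile: 256 x 256 in-plane, 400 epochs,
        the default ~4 M-parameter network, cohort-sized phantom counts."""
        return cls(grid_shape=(256, 256, 24), n_train_phantoms=150,
                   n_val_phantoms=120, epochs=400, base_channels=32,
                   n_scales=3, n_res_blocks=2, n_res_blocks_decoder=1)


def simulate_cases(n_cases: int, grid_shape, acq: AcquisitionModel, seed: int):
    """Simulate ``n_cases`` random phantoms with their duration series.

    Returns a list of ``(truth, ct, series)`` where series maps duration to
    the simulated scan; the longest duration serves as the reference.
    """
    cases = []
    ss = np.random.SeedSequence(entropy=seed)
    for child in ss.spawn(n_cases):
        s_spec, s_series = (int(x % (2 ** 31)) for x in child.generate_state(2))
        spec = random_phantom_spec(seed=s_spec, grid_shape=grid_shape)
        truth, ct = generate_phantom(spec)
        series, _ = build_duration_series(truth, ct, acq, seed=s_series)
        cases.append((truth, ct, series))
    return cases


def build_slab_pairs(cases, acq: AcquisitionModel,
                     norm: NormalizationConstants,
                     S: int = S_DEFAULT, stride: int = 2):
    """Normalized (pet, ct, target) slab triples over all short durations."""
    ref_t = max(acq.durations_s)
    pairs = []
    for truth, ct, series in cases:
        target = normalize(series[ref_t], norm)
        ct_n = normalize(ct, norm)
        tgt_stack = extract_slabs(target, S=S, stride=stride)
        ct_stack = extract_slabs(ct_n, S=S, stride=stride)
        for t in acq.durations_s:
            if t == ref_t:
                continue
            pet_stack = extract_slabs(normalize(series[t], norm), S=S,
                                      stride=stride)
            for p, c, g in zip(pet_stack.slabs, ct_stack.slabs,
                               tgt_stack.slabs):
                pairs.append((p, c, g))
    return pairs


def denoise_volume(net: RestorationNet, pet: PETVolume, ct: CTVolume | None,
                   norm: NormalizationConstants,
                   S: int = S_DEFAULT) -> PETVolume:
    """Restore a full volume: normalize, tile into slabs, predict, reassemble.

    Inference tiles with stride S (seamless; overlap only from the flush-end
    slab, removed by averaging) and returns the prediction denormalized back
    to SUV, floored at zero.
    """
    pet_n = normalize(pet, norm)
    pet_stack = extract_slabs(pet_n, S=S, stride=S)
    if net.config.use_ct_branch:
        if ct is None:
            raise ValueError("this network requires a CT volume")
        ct_stack = extract_slabs(normalize(ct, norm), S=S, stride=S)
        ct_batch = np.stack(ct_stack.slabs).astype(np.float32)[..., None]
    else:
        ct_batch = None
    pet_batch = np.stack(pet_stack.slabs).astype(np.float32)[..., None]
    pred = net.forward(pet_batch, ct_batch).data[..., 0]
    out_stack = type(pet_stack)(slabs=[p for p in pred],
                                origin_indices=pet_stack.origin_indices,
                                source_shape=pet_stack.source_shape,
                                pad_front=pet_stack.pad_front)
    restored = reassemble(out_stack)
    out = denormalize(PETVolume(restored, pet.voxel_size_mm,
                                duration_s=pet.duration_s), norm)
    out.data = np.maximum(out.data, 0.0)
    out.meta = dict(pet.meta, method="p3dnet" if net.config.use_ct_branch
                    else "3dnet")
    return out


def run_desk_experiment(profile: DeskProfile | None = None,
                        acq: AcquisitionModel | None = None,
                        loss_cfg: LossConfig | None = None,
                        methods: tuple[str, ...] = ("p3dnet", "3dnet"),
                        durations_eval: tuple[float, ...] | None = None):
    """Simulate, train and evaluate the restoration networks at desk scale.

    Trains one model per requested method on slab pairs pooled over all
    short durations, then reports the mean SSIM (against each phantom's
    simulated reference scan, on the normalized scale) of raw and restored
    validation volumes per duration.  Returns ``(ssim_table, nets, extras)``
    where ``ssim_table`` maps method -> {duration: mean SSIM} and includes
    the "raw" baseline.
    """
    from .metrics import ssim as ssim_metric

    profile = profile or DeskProfile()
    acq = acq or AcquisitionModel()
    loss_cfg = loss_cfg or LossConfig()
    ref_t = max(acq.durations_s)
    short_ts = [t for t in acq.durations_s if t != ref_t]
    eval_ts = list(durations_eval) if durations_eval else short_ts

    train_cases = simulate_cases(profile.n_train_phantoms, profile.grid_shape,
                                 acq, seed=profile.seed)
    val_cases = simulate_cases(profile.n_val_phantoms, profile.grid_shape,
                               acq, seed=profile.seed + 10_000)
    norm = fit_normalization(
        [series[t] for _, _, series in train_cases for t in acq.durations_s],
        [ct for _, ct, _ in train_cases])
    pairs = build_slab_pairs(train_cases, acq, norm,
                             stride=profile.train_stride)

    nets: dict[str, RestorationNet] = {}
    histories: dict[str, list] = {}
    for method in methods:
        use_ct = method == "p3dnet"
        net = build_network(profile.network_config(use_ct_branch=use_ct),
                            seed=profile.seed)
        tcfg = TrainConfig(epochs=profile.epochs, seed=profile.seed)
        net, hist = train(pairs, net, tcfg, loss_cfg)
        nets[method] = net
        histories[method] = hist

    ssim_table: dict[str, dict[float, float]] = {m: {} for m in
                                                 ("raw",) + tuple(methods)}
    for t in eval_ts:
        raw_vals, method_vals = [], {m: [] for m in methods}
        for truth, ct, series in val_cases:
            ref_n = normalize(series[ref_t], norm).data
            raw_n = normalize(series[t], norm).data
            raw_vals.append(ssim_metric(raw_n, ref_n))
            for m in methods:
                restored = denoise_volume(nets[m], series[t], ct, norm)
                method_vals[m].append(
                    ssim_metric(normalize(restored, norm).data, ref_n))
        ssim_table["raw"][t] = float(np.mean(raw_vals))
        for m in methods:
            ssim_table[m][t] = float(np.mean(method_vals[m]))
    extras = {"norm": norm, "histories": histories,
              "val_cases": val_cases, "profile": profile}
    return ssim_table, nets, extras
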