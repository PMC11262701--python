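"""Reproducible experiment presets and checkpoint serialization.

Each preset ties the library into one of the study protocols: the
two-regime illustration (``collapse_vs_tiling``, alias ``fig3``), the
rate-distortion sweep (``fig4_sweep``), the generalization experiment
(``fig6_generalization``), the resource-allocation analysis
(``fig7_8_allocation``) and the acoustic-frequency case study
(``fig9_acoustic``).  A preset writes tidy CSV tables plus a JSON
manifest (resolved config, seeds, version, wall clock) into the output
directory; a manifest plus the code reproduces the run.
"""

from __future__ import annotations

import dataclasses
import json
import time
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    fit_rmse_scale,
    mse_map_curve,
    neural_density,
    performance_region,
    power_law_fit,
    synthetic_limens,
)
from .decoder import DecoderParams
from .encoder import EncoderParams
from .ising import IsingParams
from .stimuli import AcousticSpectrumParams, StimulusDistribution
from .training import (
    StimulusTransform,
    TrainedModel,
    TrainingConfig,
    generalization_experiment,
    rate_distortion_sweep,
    train,
)


class UsageError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_checkpoint(model: TrainedModel, path) -> None:
    """Serialize a trained model to an .npz archive (round-trip exact)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "checkpoint_version": _CHECKPOINT_VERSION,
        "config": dataclasses.asdict(model.config),
        "transform": dataclasses.asdict(model.transform),
        "beta": model.beta,
        "stopped_epoch": model.stopped_epoch,
    }
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        amplitudes=model.encoder.amplitudes,
        centers=model.encoder.centers,
        widths=model.encoder.widths,
        h=model.prior.biases,
        couplings=model.prior.couplings,
        independent=np.array(model.prior.independent),
        w1=model.decoder.w1,
        b1=model.decoder.b1,
        w2=model.decoder.w2,
        b2=model.decoder.b2,
    )


def load_checkpoint(path) -> TrainedModel:
    """Load a checkpoint written by :func:`save_checkpoint`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"].tobytes()).decode())
            if meta.get("checkpoint_version") != _CHECKPOINT_VERSION:
                raise UsageError(
                    f"unsupported checkpoint version {meta.get('checkpoint_version')}"
                )
            cfg = TrainingConfig(**meta["config"])
            enc = EncoderParams(z["amplitudes"], z["centers"], z["widths"])
            prior = IsingParams(
                z["h"], z["couplings"], independent=bool(z["independent"])
            )
            dec = DecoderParams(
                family=cfg.decoder_family,
                w1=z["w1"],
                b1=z["b1"],
                w2=z["w2"],
                b2=z["b2"],
                nonlinearity=cfg.nonlinearity,
                sigma2_floor=cfg.sigma2_floor,
                map_mode=cfg.map_mode,
            )
    except (OSError, ValueError, KeyError, zipfile.BadZipFile) as err:
        if isinstance(err, UsageError):
            raise
        raise UsageError(f"corrupt or truncated checkpoint {path}: {err}") from err
    return TrainedModel(
        config=cfg,
        encoder=enc,
        prior=prior,
        decoder=dec,
        transform=StimulusTransform(**meta["transform"]),
        beta=float(meta["beta"]),
        history=pd.DataFrame(),
        stopped_epoch=int(meta["stopped_epoch"]),
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def _acoustic_distribution() -> StimulusDistribution:
    return StimulusDistribution.from_spectrum(AcousticSpectrumParams())


def _preset_fig3(opts: dict, out: Path) -> dict:
    """Two qualitative regimes: collapsed (low rate) vs tiling (high rate)."""
    dist = StimulusDistribution.gaussian(0.0, 5.0)
    cfg = TrainingConfig(
        n_neurons=opts.get("n_neurons", 10),
        decoder_family="gaussian",
        max_epochs=opts.get("max_epochs", 1500),
        seed=opts.get("seed", 0),
    )
    rows = []
    for label, rbar in (("collapsed", 0.0), ("tiling", opts.get("high_rate", 4.0))):
        model = train(dataclasses.replace(cfg, target_rate=rbar), dist)
        x_eval = dist.sample(cfg.n_test, np.random.default_rng(cfg.seed + 101))
        rep = model.evaluate(x_eval)
        kl, _ = model.kl_from_stimulus(dist, cfg.n_test, cfg.seed + 102)
        rows.append(
            {
                "regime": label,
                "target_rate": rbar,
                "distortion": rep.distortion,
                "rate": rep.rate,
                "neg_elbo": rep.neg_elbo,
                "kl": kl,
                "mean_amplitude": float(np.mean(model.amplitudes)),
                "mean_width": float(np.mean(model.widths)),
            }
        )
        save_checkpoint(model, out / f"fig3_{label}.npz")
    frame = pd.DataFrame(rows)
    frame.to_csv(out / "fig3_regimes.csv", index=False)
    return {"tables": ["fig3_regimes.csv"], "stimulus_entropy": dist.entropy()}


def _preset_fig4(opts: dict, out: Path) -> dict:
    dist = StimulusDistribution.lognormal(1.0, 1.0)
    cfg = TrainingConfig(
        n_neurons=opts.get("n_neurons", 12),
        decoder_family=opts.get("decoder_family", "gaussian"),
        prior_kind=opts.get("prior_kind", "ising"),
        max_epochs=opts.get("max_epochs", 1000),
    )
    rbars = opts.get("target_rates", [0.25, 0.75, 1.32, 2.0, 3.0, 4.0])
    seeds = opts.get("seeds", list(range(2)))
    frame, _ = rate_distortion_sweep(cfg, dist, rbars, seeds)
    frame.to_csv(out / "fig4_sweep.csv", index=False)
    return {"tables": ["fig4_sweep.csv"], "stimulus_entropy": dist.entropy()}


def _preset_fig6(opts: dict, out: Path) -> dict:
    dist = StimulusDistribution.lognormal(1.0, 1.0)
    cfg = TrainingConfig(
        n_neurons=opts.get("n_neurons", 12),
        max_epochs=opts.get("max_epochs", 800),
    )
    frame = generalization_experiment(
        cfg,
        dist,
        opts.get("train_sizes", [100, 2000]),
        opts.get("target_rates", [0.5, 3.0]),
        opts.get("seeds", list(range(2))),
    )
    frame.to_csv(out / "fig6_generalization.csv", index=False)
    return {"tables": ["fig6_generalization.csv"]}


def _allocation_summary(models, dist, grid) -> dict:
    """Pooled density / width / error power-law fits for one target rate."""
    centers = np.concatenate([m.centers for m in models])
    widths = np.concatenate([m.widths for m in models])
    curve = np.mean([mse_map_curve(m, grid) for m in models], axis=0)
    region = performance_region(grid, curve, dist.variance())
    dens = neural_density(centers, grid)
    in_region = (grid >= region[0]) & (grid <= region[1])
    out = {"region": region}
    fits = {
        "density": power_law_fit(grid[in_region], dens[in_region], dist, region, "density"),
        "width": power_law_fit(centers, widths, dist, region, "width"),
        "error": power_law_fit(grid[in_region], curve[in_region], dist, region, "error"),
    }
    for name, fit in fits.items():
        out[name] = {
            "gamma": fit.gamma,
            "r_squared": fit.r_squared,
            "reliable": fit.reliable,
        }
    mask_c = (centers >= region[0]) & (centers <= region[1])
    if mask_c.sum() >= 3:
        dens_at_centers = neural_density(centers, centers[mask_c])
        out["width_density_corr"] = float(
            np.corrcoef(dens_at_centers, widths[mask_c])[0, 1]
        )
    return out


def _preset_fig7_8(opts: dict, out: Path) -> dict:
    dist = StimulusDistribution.lognormal(1.0, 1.0)
    cfg = TrainingConfig(
        n_neurons=opts.get("n_neurons", 12),
        max_epochs=opts.get("max_epochs", 1000),
    )
    rbars = opts.get("target_rates", [0.5, 1.5, 3.0])
    seeds = opts.get("seeds", list(range(4)))
    frame, models = rate_distortion_sweep(cfg, dist, rbars, seeds, keep_models=True)
    frame.to_csv(out / "fig7_8_sweep.csv", index=False)
    grid = np.quantile(
        dist.sample(4000, 915), np.linspace(0.02, 0.98, opts.get("n_grid", 40))
    )
    summary = {}
    for rbar in rbars:
        group = [m for (r, _), m in models.items() if r == float(rbar)]
        try:
            summary[f"target_rate={rbar}"] = _allocation_summary(group, dist, grid)
        except Exception as err:  # fit may fail at extreme rates
            summary[f"target_rate={rbar}"] = {"error": str(err)}
    (out / "fig7_8_fits.json").write_text(json.dumps(summary, indent=2))
    return {"tables": ["fig7_8_sweep.csv", "fig7_8_fits.json"]}


def _preset_fig9(opts: dict, out: Path) -> dict:
    dist = _acoustic_distribution()
    family = opts.get("decoder_family", "lognormal")
    cfg = TrainingConfig(
        n_neurons=opts.get("n_neurons", 12),
        decoder_family=family,
        target_rate=opts.get("target_rate", 2.0),
        max_epochs=opts.get("max_epochs", 1000),
    )
    seeds = opts.get("seeds", list(range(2)))
    kls, curves = [], []
    freqs, limens = synthetic_limens()
    for seed in seeds:
        model = train(dataclasses.replace(cfg, seed=int(seed)), dist)
        kl, _ = model.kl_from_stimulus(dist, cfg.n_test, int(seed) + 511)
        kls.append(kl)
        curves.append(np.sqrt(mse_map_curve(model, freqs)))
        save_checkpoint(model, out / f"fig9_{family}_seed{seed}.npz")
    rmse = np.mean(curves, axis=0)
    scale = fit_rmse_scale(limens, rmse)
    table = pd.DataFrame(
        {
            "frequency_hz": freqs,
            "limen_hz_synthetic": limens,
            "rmse_hz": rmse,
            "rmse_scaled": rmse / scale.scale,
        }
    )
    table.to_csv(out / f"fig9_{family}_rmse.csv", index=False)
    return {
        "tables": [f"fig9_{family}_rmse.csv"],
        "kl_mean": float(np.mean(kls)),
        "kl_per_seed": [float(k) for k in kls],
        "rmse_scale_factor": scale.scale,
        "rmse_scale_r2": scale.r_squared,
    }


PRESETS = {
    "fig3": _preset_fig3,
    "fig4_sweep": _preset_fig4,
    "fig6_generalization": _preset_fig6,
    "fig7_8_allocation": _preset_fig7_8,
    "fig9_acoustic": _preset_fig9,
}


def run_preset(name: str, overrides: dict | None = None, out_dir="runs") -> dict:
    """Execute a named preset and write its outputs plus a manifest.

    ``overrides`` tunes the protocol scale (seeds, epochs, target rates,
    population size) without changing its structure.  Returns the
    manifest dictionary.
    """
    if name not in PRESETS:
        raise UsageError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    opts = dict(overrides or {})
    out = Path(out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    result = PRESETS[name](opts, out)
    manifest = {
        "preset": name,
        "overrides": opts,
        "version": __version__,
        "wall_clock_s": round(time.time() - t0, 2),
        "output_dir": str(out),
        **result,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
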