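"""Pipeline orchestration: run the four analysis stages from one config.

A run config (YAML/dict) selects stages (itc, mst, nmr, ms), gives each
stage either a ``simulate`` block or an input file, and carries a seed.
Each stage writes its tables into the output directory; the run ends
with a ``summary.json`` that is byte-identical across reruns of the
same config and seed, and a log file carrying versions, timing and the
config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, itc_onesite, mst_binding, native_ms, nmr_relaxation
from . import synthetic_data as synth
from .itc_onesite import OneSiteModel, TitrationProtocol
from .nmr_relaxation import FieldContext, ModelFreeParams

log = logging.getLogger("bindkit")

_TOP_KEYS = {"seed", "stages"}
_STAGE_KEYS = {"itc", "mst", "nmr", "ms"}
_ITC_KEYS = {"simulate", "input", "protocol", "init", "skip_first"}
_MST_KEYS = {"simulate", "input", "target_conc_M", "init_kd_M"}
_NMR_KEYS = {"simulate", "input", "field_T", "noe_min", "n_mc", "exchange"}
_MS_KEYS = {"simulate", "input", "component_masses_Da", "tolerance_Da", "max_copies"}


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set, where: str) -> None:
    for key in block:
        if key not in allowed:
            raise ConfigError(f"unknown config key {key!r} in {where}")


def config_hash(config: dict) -> str:
    """Stable hash of a config dict (order-insensitive)."""
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    return cfg


def _stage_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _noise_from(block: dict | None, seed: int) -> synth.NoiseSpec:
    if not block:
        return synth.NoiseSpec()
    return synth.NoiseSpec(
        kind=block.get("kind", "none"),
        scale=float(block.get("scale", 0.0)),
        seed=seed,
    )


def _run_itc(block: dict, seed: int, outdir: Path) -> dict:
    _check_keys(block, _ITC_KEYS, "stages.itc")
    protocol = TitrationProtocol(**block.get("protocol", {}))
    if "simulate" in block:
        sim = dict(block["simulate"])
        noise = _noise_from(sim.pop("noise", None), seed)
        truth = OneSiteModel(
            n=float(sim.pop("n")),
            kd_m=float(sim.pop("Kd_M")),
            dh_kcal_mol=float(sim.pop("dH_kcal_mol")),
        )
        if sim:
            raise ConfigError(f"unknown config key {next(iter(sim))!r} in stages.itc.simulate")
        table = synth.gen_itc_heats(truth, protocol, noise)
        table.to_csv(outdir / "itc_heats.csv", index=False)
    else:
        table = itc_onesite.read_heats_csv(block["input"])
    init_block = block.get("init", {})
    init = OneSiteModel(
        n=float(init_block.get("n", 1.0)),
        kd_m=float(init_block.get("Kd_M", 1e-6)),
        dh_kcal_mol=float(init_block.get("dH_kcal_mol", 1.0)),
    )
    fit = itc_onesite.fit_one_site(
        table["heat_ucal"].to_numpy(),
        protocol,
        init,
        skip_first=bool(block.get("skip_first", True)),
    )
    return fit.to_dict()


def _run_mst(block: dict, seed: int, outdir: Path) -> dict:
    _check_keys(block, _MST_KEYS, "stages.mst")
    if "simulate" in block:
        sim = dict(block["simulate"])
        noise = _noise_from(sim.pop("noise", None), seed)
        series = synth.gen_mst_series(
            kd_m=float(sim.pop("Kd_M")),
            target_conc_m=float(sim.pop("target_conc_M")),
            top_ligand_m=float(sim.pop("top_ligand_M")),
            n_points=int(sim.pop("n_points", 16)),
            plateaus=tuple(sim.pop("plateaus", (800.0, 900.0))),
            noise=noise,
        )
        if sim:
            raise ConfigError(f"unknown config key {next(iter(sim))!r} in stages.mst.simulate")
        mst_binding.write_series_csv(outdir / "mst_series.csv", series)
        series_list = [series]
    else:
        series_list = mst_binding.read_series_csv(
            block["input"], float(block["target_conc_M"])
        )
    fit = mst_binding.fit_kd(series_list, block.get("init_kd_M"))
    return fit.to_dict()


def _run_nmr(block: dict, seed: int, outdir: Path) -> dict:
    _check_keys(block, _NMR_KEYS, "stages.nmr")
    field = FieldContext(b0_t=float(block["field_T"]))
    n_mc = int(block.get("n_mc", 200))
    if "simulate" in block:
        sim = dict(block["simulate"])
        noise = _noise_from(sim.pop("noise", None), seed)
        params = ModelFreeParams(
            tau_r_s=float(sim.pop("tau_r_ns")) * 1e-9,
            s2=float(sim.pop("s2", 0.85)),
            tau_e_s=float(sim.pop("tau_e_ps", 20.0)) * 1e-12,
        )
        residues = list(range(1, int(sim.pop("n_residues", 50)) + 1))
        if sim:
            raise ConfigError(f"unknown config key {next(iter(sim))!r} in stages.nmr.simulate")
        amp_table, noe_table = synth.gen_relaxation_decays(
            params, field, residues, noise=noise
        )
        amp_table.to_csv(outdir / "relaxation_amplitudes.tsv", sep="\t", index=False)
    else:
        amp_table = pd.read_csv(block["input"], sep="\t")
        noe_table = None
    rates = nmr_relaxation.fit_rates_from_table(amp_table, n_mc=n_mc, seed=seed)
    if noe_table is not None:
        noes = [
            nmr_relaxation.compute_noe(r.I_sat, r.I_ref)[0]
            for r in noe_table.itertuples()
        ]
        rates["NOE"] = noes
    rates.to_csv(outdir / "relaxation_rates.tsv", sep="\t", index=False)
    summary: dict = {
        "R1_mean_s1": float(rates["R1_s1"].mean()),
        "R2_mean_s1": float(rates["R2_s1"].mean()),
    }
    if "NOE" in rates:
        rate_set = nmr_relaxation.RelaxationRateSet(
            residues=rates["residue"].to_numpy(),
            r1=rates["R1_s1"].to_numpy(),
            r2=rates["R2_s1"].to_numpy(),
            noe=rates["NOE"].to_numpy(),
        )
        tau_r, sem, n_used = nmr_relaxation.overall_tau_r(
            rate_set, field, noe_min=float(block.get("noe_min", 0.75))
        )
        summary.update(
            {"tauR_ns": tau_r * 1e9, "tauR_sem_ns": sem * 1e9, "n_residues_used": n_used}
        )
        sdm = nmr_relaxation.reduced_sdm(
            rate_set.r1, rate_set.r2, rate_set.noe, field
        )
        pd.DataFrame(
            {
                "residue": rate_set.residues,
                "J0_s_rad": sdm.j0,
                "JwN_s_rad": sdm.j_wn,
                "JwH087_s_rad": sdm.j_wh087,
            }
        ).to_csv(outdir / "sdm.tsv", sep="\t", index=False)
    if "exchange" in block:
        ex = dict(block["exchange"])
        model = nmr_relaxation.ExchangeTwoState(
            tau_r_free_s=float(ex.get("tau_r_free_ns", summary.get("tauR_ns"))) * 1e-9,
            tau_r_bound_s=float(ex["tau_r_bound_ns"]) * 1e-9,
            tau_r_obs_s=float(ex["tau_r_obs_ns"]) * 1e-9,
            convention=ex.get("convention", "linear_tau"),
        )
        summary["p_bound"] = nmr_relaxation.exchange_population(model)
        summary["tauR_free_ns"] = model.tau_r_free_s * 1e9
        summary["tauR_obs_ns"] = model.tau_r_obs_s * 1e9
    return summary


def _run_ms(block: dict, seed: int, outdir: Path) -> dict:
    _check_keys(block, _MS_KEYS, "stages.ms")
    if "simulate" in block:
        sim = dict(block["simulate"])
        jitter = _noise_from(sim.pop("mz_jitter", None), seed)
        mass = float(sim.pop("mass_Da"))
        charges = range(int(sim.pop("z_min", 15)), int(sim.pop("z_max", 22)) + 1)
        if sim:
            raise ConfigError(f"unknown config key {next(iter(sim))!r} in stages.ms.simulate")
        peaks = synth.gen_esi_envelope(mass, charges, mz_jitter=jitter)
        native_ms.write_peaklist_csv(outdir / "esi_peaks.csv", peaks)
    else:
        peaks = native_ms.read_peaklist_csv(block["input"])
    charges = native_ms.infer_charge_states(peaks)
    mass, spread = native_ms.reconstruct_zero_charge(peaks, charges)
    out: dict = {
        "mass_Da": mass,
        "spread_Da": spread if np.isfinite(spread) else None,
        "charges": [int(z) for z in charges],
    }
    if "component_masses_Da" in block:
        assignment = native_ms.assign_stoichiometry(
            mass,
            {k: float(v) for k, v in block["component_masses_Da"].items()},
            tolerance_da=float(block.get("tolerance_Da", 10.0)),
            max_copies=int(block.get("max_copies", 4)),
        )
        out["stoichiometry"] = assignment.stoichiometry
        out["mass_error_Da"] = assignment.mass_error_da
    return out


_RUNNERS = {"itc": _run_itc, "mst": _run_mst, "nmr": _run_nmr, "ms": _run_ms}


def run_pipeline(config: dict, outdir, seed: int | None = None) -> dict:
    """Execute the configured stages and write tables plus summary.json.

    Stage failures are isolated: a failing stage is recorded under
    ``errors`` and the remaining stages still run; the caller decides
    the exit status from the presence of errors.
    """
    _check_keys(config, _TOP_KEYS, "top level")
    stages = config.get("stages", {})
    _check_keys(stages, _STAGE_KEYS, "stages")
    if seed is None:
        seed = int(config.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    summary: dict = {"seed": seed, "config_hash": config_hash(config)}
    errors: dict = {}
    timings: dict = {}
    for name, runner in _RUNNERS.items():
        if name not in stages:
            continue
        t0 = time.perf_counter()
        try:
            summary[name] = runner(stages[name], _stage_seed(seed, name), outdir)
            log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)
        except ConfigError:
            raise  # a bad config is the caller's error, not a stage failure
        except Exception as exc:  # stage isolation
            log.error("stage %s failed: %s", name, exc)
            errors[name] = str(exc)
        timings[name] = round(time.perf_counter() - t0, 3)
    if errors:
        summary["errors"] = errors
    write_report(summary, outdir, config=config, timings=timings)
    return summary


def write_report(
    summary: dict, outdir, config: dict | None = None, timings: dict | None = None
) -> Path:
    """Write summary.json (deterministic bytes) and a run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    lines = [
        f"bindkit {__version__} on python {platform.python_version()}",
        f"numpy {np.__version__}, pandas {pd.__version__}",
    ]
    if config is not None:
        lines.append(f"config hash: {config_hash(config)}")
    if timings:
        lines.extend(f"stage {k}: {v} s" for k, v in timings.items())
    (outdir / "run.log").write_text("\n".join(lines) + "\n")
    return path


def read_summary(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
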