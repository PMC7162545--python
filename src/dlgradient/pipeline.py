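"""End-to-end orchestration: synthetic cohort -> quantification -> screen.

A single YAML/dict config drives the stages; every stochastic component is
seeded from a master seed through a stable per-stage derivation, so a full
run is a pure function of the config and re-running it reproduces every
output byte for byte.  Each run emits a manifest listing the outputs with
SHA-256 checksums.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .borders import load_observations
from .dosage_stats import (
    DosageSeries,
    bootstrap_amplitude_ratios,
    canonical_amplitude_curve,
    loglog_sensitivity,
    qpcr_weighted_stats,
    relative_abundance,
)
from .profiles import CanonicalProfile, fit_dl_gradient, fit_gene_borders
from .screen import ScreenConfig, run_screen, summarize_ensemble
from .synth import GENOTYPE_DOSAGE, SynthConfig, synth_embryo_profiles, \
    synth_gene_profiles, synth_amplitude_traces, synth_qpcr

__all__ = ["run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("synth", "quantify", "amplitude", "qpcr", "screen")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(master: int, stage: str) -> int:
    # stable per-stage derivation, kept below 2**31
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Execute the requested stages in dependency order.

    ``config`` keys: ``seed`` (master seed, default 0), ``stages`` (subset of
    DEFAULT_STAGES, default all), ``n_embryos``, ``screen_n_sets``.  Returns
    the run manifest (also written to ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = list(config.get("stages", DEFAULT_STAGES))
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "config": {k: v for k, v in config.items()},
        "outputs": {},
        "timing": {},
    }

    synth_cfg = SynthConfig(
        seed=_stage_seed(seed, "synth"),
        n_embryos=int(config.get("n_embryos", 40)),
    )
    profiles = genes = traces = qpcr_table = None

    for stage in stages:
        t0 = time.perf_counter()
        if stage == "synth":
            profiles, grad_truth = synth_embryo_profiles(synth_cfg)
            genes, gene_truth = synth_gene_profiles(synth_cfg)
            traces, trace_truth = synth_amplitude_traces(synth_cfg)
            qpcr_table, qpcr_truth = synth_qpcr(synth_cfg)
            rows = [
                {"embryo_id": p.meta["embryo_id"], "genotype": p.meta["genotype"],
                 "channel": p.meta["channel"], "x": xi, "intensity": yi}
                for p in profiles
                for xi, yi in zip(p.x, p.intensity)
            ]
            pd.DataFrame(rows).to_csv(out / "dl_profiles.csv", index=False)
            qpcr_table.to_csv(out / "qpcr.csv", index=False)
            _write_json(
                out / "truth.json",
                {"gradients": grad_truth, "genes": gene_truth,
                 "traces": trace_truth, "qpcr": qpcr_truth},
            )
        elif stage == "quantify":
            if profiles is None:
                raise RuntimeError("'quantify' requires the 'synth' stage")
            fits = []
            for p in profiles:
                f = fit_dl_gradient(p)
                fits.append(
                    {"embryo_id": p.meta["embryo_id"],
                     "genotype": p.meta["genotype"],
                     "sigma": f.sigma, "A": f.A, "B": f.B, "M": f.M,
                     "mu": f.mu, "gof": f.gof}
                )
            fit_df = pd.DataFrame(fits)
            fit_df = fit_df[fit_df.gof >= 0.7]
            fit_df.to_csv(out / "gradient_fits.csv", index=False)
            series = DosageSeries(
                {
                    GENOTYPE_DOSAGE[g]: grp["sigma"].to_numpy()
                    for g, grp in fit_df.groupby("genotype")
                }
            )
            slope = loglog_sensitivity(series)
            border_rows = []
            for p in genes:
                gene = p.meta["channel"]
                kind = "ventral" if gene == "sna" else "lateral"
                bf = fit_gene_borders(p, CanonicalProfile(kind=kind))
                if bf.excluded:
                    continue
                for k, b in enumerate(bf.borders):
                    border_rows.append(
                        {"embryo_id": p.meta["embryo_id"], "gene": gene,
                         "genotype": p.meta["genotype"], "edge": k,
                         "border": b, "gof": bf.gof}
                    )
            pd.DataFrame(border_rows).to_csv(out / "gene_borders.csv", index=False)
            _write_json(
                out / "width_sensitivity.json",
                {"slope": slope.slope, "ci68": slope.ci68, "n": slope.n},
            )
        elif stage == "amplitude":
            if traces is None:
                raise RuntimeError("'amplitude' requires the 'synth' stage")
            tau, canonical, peaks = canonical_amplitude_curve(traces)
            by_geno: dict[str, list[float]] = {}
            for tr, pk in zip(traces, peaks):
                by_geno.setdefault(tr.meta["genotype"], []).append(pk)
            boot_seed = _stage_seed(seed, "bootstrap")
            ratios = {}
            for g in ("1x", "4x"):
                m, s, _ = bootstrap_amplitude_ratios(
                    np.array(by_geno[g]), np.array(by_geno["2x"]), seed=boot_seed
                )
                ratios[f"{g}_2x"] = {"mean": m, "sd": s}
            _write_json(out / "amplitude_ratios.json", ratios)
            pd.DataFrame({"tau": tau, "canonical": canonical}).to_csv(
                out / "canonical_curve.csv", index=False
            )
        elif stage == "qpcr":
            if qpcr_table is None:
                raise RuntimeError("'qpcr' requires the 'synth' stage")
            stats = qpcr_weighted_stats(qpcr_table)
            folds = relative_abundance(stats)
            stats.join(folds).to_csv(out / "qpcr_stats.csv")
        elif stage == "screen":
            cfg = ScreenConfig(
                n_sets=int(config.get("screen_n_sets", 500)),
                seed=_stage_seed(seed, "screen"),
                observations=tuple(load_observations()),
            )
            records = run_screen(cfg, out_path=out / "records.ndjson")
            _write_json(out / "summary.json", summarize_ensemble(records))
        else:
            raise ValueError(f"unknown stage {stage!r}")
        manifest["timing"][stage] = round(time.perf_counter() - t0, 3)

    for path in sorted(out.glob("*")):
        if path.name == "manifest.json" or path.is_dir():
            continue
        manifest["outputs"][path.name] = _sha256(path)
    _write_json(out / "manifest.json", manifest)
    return manifest
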