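"""End-to-end synthetic reproduction: generate -> analyze -> fit -> summarize.

``run_pipeline`` executes the behavioural and spiking generators, the
periodicity/phase analyses and the observer-model comparison at a reduced
scale, writing a machine-readable manifest.  Every stochastic stage draws
its own named seed from the run seed, so a fixed configuration reproduces
the manifest exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from . import observer, periodicity, phase, synthetic, task
from .io import RunConfig, save_session

__all__ = ["run_pipeline"]


def _seed_for(base: int, name: str) -> int:
    import zlib

    h = zlib.crc32(name.encode())  # process-independent, unlike hash()
    return int(np.random.SeedSequence([base, h]).generate_state(1)[0] % (2**31 - 1))


def run_pipeline(config: RunConfig | None = None, out_dir=None) -> dict:
    """Run the reduced end-to-end synthetic pipeline; returns the manifest."""
    cfg = config or RunConfig()
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg.__dict__.copy(), "stages": {}}

    def stage(name, fn):
        try:
            manifest["stages"][name] = {"status": "ok", **fn()}
        except Exception as exc:  # partial manifest with stage status
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}

    obs = observer.ObserverParams(w_m=0.05, w_p=0.08, offset_b=0.0,
                                  model_kind="subscalar", t_o=cfg.t_o)
    trials = synthetic.gen_behavior_session(
        obs, n_trials=cfg.n_trials, seed=_seed_for(cfg.seed, "behavior"))

    def behavior():
        perf = task.performance_slope(trials)
        return {"n_trials": int(len(trials)),
                "slope": perf["slope"], "intercept": perf["intercept"]}

    stage("behavior", behavior)

    pop = synthetic.PopulationSpec(
        [synthetic.make_class_spec("periodic") for _ in range(cfg.n_neurons // 2)]
        + [synthetic.make_class_spec("ramping") for _ in range(cfg.n_neurons - cfg.n_neurons // 2)],
        seed=_seed_for(cfg.seed, "pop"),
    )
    sessions = synthetic.gen_spike_session(pop, trials,
                                           seed=_seed_for(cfg.seed, "spikes"))

    def periodicity_stage():
        peaks, sig = [], 0
        for i, nrn in enumerate(sessions[: cfg.n_neurons // 2]):
            res = periodicity.classify_periodic(
                nrn, n_null=cfg.n_null, seed=_seed_for(cfg.seed, f"null{i}"))
            if res.significant:
                sig += 1
                peaks.append(res.peak_lag)
        return {"n_significant": sig,
                "median_peak_lag": float(np.median(peaks)) if peaks else None}

    stage("periodicity", periodicity_stage)

    def phase_stage():
        res = phase.phase_null_and_test(
            sessions[0], seed=_seed_for(cfg.seed, "phase"))
        return {"phi1": res.phases[0],
                "ks_p_first_peak": res.ks[0][1], "retained": res.retained}

    stage("phase", phase_stage)

    def observer_stage():
        cmp = observer.compare_models([
            observer.simulate_trials(obs, n=cfg.n_trials,
                                     seed=_seed_for(cfg.seed, f"obs{k}"))
            for k in range(4)
        ])
        return {"winner": cmp["winner"], "t": cmp.get("t"), "p": cmp.get("p")}

    stage("observer", observer_stage)

    save_session(trials, sessions, out / "session")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
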