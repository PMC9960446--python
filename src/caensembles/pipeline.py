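"""End-to-end pipeline driver: simulate/load -> classify -> subtype -> Moran ->
decode, with every stochastic stage seeded from one top-level seed via named
substreams and all outputs written as TSV plus a text summary."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import BEHAVIOR_POKING, BEHAVIOR_REWARD
from .decoding import DecodeConfig, decode_all_configurations
from .ensembles import ClassifierConfig, classify_population, ensemble_members
from .io import read_session, write_labels, write_session
from .spatial import morans_test
from .subtypes import SubtypeConfig, subtype_population
from .synthetic import NeuronSpec, SessionConfig, simulate_session

__all__ = ["default_config", "specs_from_counts", "run_pipeline"]

# substream tags so stages draw from independent streams of the same seed
_STREAMS = {"simulate": 0, "classify": 1, "subtype": 2, "moran": 3, "decode": 4}


def default_config() -> dict:
    """Small demo configuration exercising every stage."""
    return {
        "schema_version": 1,
        "seed": 0,
        "simulate": {
            "n_trials": 60,
            "neurons": {
                "Trigger-like": 4,
                "Attention-like": 4,
                "Reward-pursuing": 4,
                "Rewarded": 4,
                "Poking-OFF": 4,
                "Reward-OFF": 4,
                "Other": 26,
            },
            "amplitude": 5.0,
        },
        "classify": {"n_permutations": 500},
        "subtype": {"n_perm": 300},
        "moran": {"n_perm": 499},
        "decode": {"n_folds": 10},
    }


def specs_from_counts(counts: dict[str, int], amplitude: float = 5.0) -> list[NeuronSpec]:
    specs = []
    for cls, n in counts.items():
        specs.extend(NeuronSpec(tuning_class=cls, response_amplitude=amplitude) for _ in range(n))
    return specs


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise ValueError("pipeline config must be a mapping or a YAML file path")
    version = config.get("schema_version", 1)
    if version != 1:
        raise ValueError(f"unsupported config schema_version {version}")
    return config


def run_pipeline(config, out_dir: str | Path, seed: int | None = None) -> Path:
    """Run the configured stages and write a report directory.

    Any stage failure aborts with the stage name and the seed it ran under.
    """
    config = _load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0) if seed is None else seed)
    log: list[str] = [f"top-level seed: {seed}"]

    def run_stage(name, fn):
        try:
            log.append(f"stage {name}: seed substream {seed}/{_STREAMS[name]}")
            return fn()
        except Exception as exc:  # noqa: BLE001 - reraise with stage context
            raise RuntimeError(f"stage '{name}' failed under seed {seed}: {exc}") from exc

    sim_cfg = config.get("simulate")
    if sim_cfg:
        def _simulate():
            counts = sim_cfg.get("neurons", default_config()["simulate"]["neurons"])
            session_config = SessionConfig(
                n_trials=int(sim_cfg.get("n_trials", 100)),
                seed=int(np.random.default_rng([seed, _STREAMS["simulate"]]).integers(2**31)),
            )
            specs = specs_from_counts(counts, float(sim_cfg.get("amplitude", 5.0)))
            bundle, truth = simulate_session(session_config, specs)
            write_session(bundle, out_dir / "session")
            return bundle
        bundle = run_stage("simulate", _simulate)
    else:
        session_dir = config.get("session_dir")
        if not session_dir:
            raise ValueError("config has no 'simulate' section and no 'session_dir' to load")
        bundle = read_session(session_dir)

    cls_cfg = config.get("classify", {})
    clf_config = ClassifierConfig(
        n_permutations=int(cls_cfg.get("n_permutations", 5000)),
        seed=int(np.random.default_rng([seed, _STREAMS["classify"]]).integers(2**31)),
    )
    labels = run_stage("classify", lambda: classify_population(bundle, config=clf_config))
    write_labels(labels, out_dir / "labels.tsv")

    if config.get("subtype") is not None:
        sub_cfg = config.get("subtype") or {}
        sub_config = SubtypeConfig(
            n_perm=int(sub_cfg.get("n_perm", 1000)),
            seed=int(np.random.default_rng([seed, _STREAMS["subtype"]]).integers(2**31)),
        )
        subtypes = run_stage(
            "subtype", lambda: subtype_population(bundle, labels, sub_config)
        )
        write_labels(subtypes, out_dir / "subtypes.tsv")
    else:
        subtypes = pd.DataFrame()

    moran_cfg = config.get("moran")
    moran_rows = []
    if moran_cfg is not None:
        def _moran():
            coords = bundle.rois[["x_px", "y_px"]].to_numpy()
            m_seed = int(np.random.default_rng([seed, _STREAMS["moran"]]).integers(2**31))
            for behavior in (BEHAVIOR_POKING, BEHAVIOR_REWARD):
                for polarity in ("ON", "OFF"):
                    members = ensemble_members(labels, behavior, polarity)
                    x = np.zeros(bundle.n_neurons)
                    x[members] = 1.0
                    if members.size == 0 or members.size == bundle.n_neurons:
                        continue
                    res = morans_test(
                        x, coords, n_perm=int(moran_cfg.get("n_perm", 999)), seed=m_seed
                    )
                    moran_rows.append(
                        (behavior, polarity, res.n_members, res.i, res.p_perm, res.z_analytic)
                    )
            return pd.DataFrame(
                moran_rows,
                columns=["behavior", "ensemble", "N_members", "I", "p_perm", "z_analytic"],
            )
        moran_df = run_stage("moran", _moran)
        write_labels(moran_df, out_dir / "moran.tsv")

    dec_cfg = config.get("decode")
    if dec_cfg is not None:
        decode_config = DecodeConfig(
            n_folds=int(dec_cfg.get("n_folds", 10)),
            balance_sizes=bool(dec_cfg.get("balance", False)),
            seed=int(np.random.default_rng([seed, _STREAMS["decode"]]).integers(2**31)),
        )
        decode_df = run_stage(
            "decode", lambda: decode_all_configurations(bundle, labels, config=decode_config)
        )
        decode_df = decode_df.assign(
            fold_accuracies=decode_df["fold_accuracies"].map(
                lambda f: ",".join(f"{a:.4f}" for a in f)
            )
        )
        write_labels(decode_df, out_dir / "decode.tsv")

    summary = [
        f"session: {bundle.session_id} ({bundle.n_neurons} neurons, {bundle.n_frames} frames)",
        "note: a neuron ON for both behaviors is counted in both ensembles;",
        "ensemble proportions therefore need not sum to 1.",
        *log,
        "",
        "ensemble sizes:",
    ]
    for behavior in bundle.behaviors:
        for polarity in ("ON", "OFF"):
            n = ensemble_members(labels, behavior, polarity).size
            summary.append(f"  {behavior} {polarity}: {n}")
    (out_dir / "summary.txt").write_text("\n".join(summary) + "\n")
    return out_dir
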