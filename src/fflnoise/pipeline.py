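"""Catalog-wide experiments: build every model, run a moment engine, and
emit the comparison tables behind each figure-style analysis.

Everything is CSV-first and deterministic: LNA sweeps are exactly
reproducible, SSA sweeps reproducible given seeds.  Each named analysis
(``fig2`` .. ``fig7``, ``s5``, ``s7``) reruns exactly the models that enter
the corresponding comparison and reports a machine-checkable verdict for
that comparison's qualitative claim alongside the tidy table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .catalog import CatalogEntry, full_catalog, get_entry
from .crn import (
    CRNModel,
    ParameterSet,
    build_model,
    with_input_mechanism,
)
from .input_signal import (
    InputProtocol,
    calibrate_input,
    set_input_noise,
    staircase,
)
from .lna import LNAResult, integrate, stationary
from .metrics import (
    ModelSummary,
    OUTPUT_SPECIES,
    REFERENCE_INPUT,
    cv_percent,
    layer_cv_profile,
    plateau_frame,
    rank_models,
    saturation_check,
    summarize,
)
from .ssa import ensemble

log = logging.getLogger("fflnoise")

#: The best-performing models singled out for the head-to-head comparison:
#: the top noise reducers and top signal transducers of the catalog-wide
#: sweep (isolated and coupled, OR-gated).
BEST_PERFORMERS = [
    "c1-OR",
    "i4-OR",
    "c4-OR",
    "c1c1-minp-OR",
    "c1i4-minp-OR",
    "c4c4-minp-OR",
    "c4i1-minp-OR",
    "c1c1-mint-OR",
    "c1i4-mint-OR",
    "c4c4-mint-OR",
]

#: Good/bad noise-reducer pairs used for the layer-wise noise profiles.
LAYER_PROFILE_MODELS = [
    "c1-OR",
    "c3-OR",
    "c1c1-minp-OR",
    "c3c3-minp-OR",
    "c1i4-mint-OR",
    "c3i2-mint-OR",
]


@dataclass
class RunConfig:
    """Fully resolved configuration of a catalog sweep."""

    families: list[str] = field(
        default_factory=lambda: ["isolated", "chain", "minp", "mint"]
    )
    scheme: str = "one-step"
    method: str = "lna"  # "lna" (stationary per plateau) or "ssa"
    drop_rule: str = "none"
    levels: list[float] = field(default_factory=lambda: [2, 3, 4, 5, 6])
    baseline: float = 1.0
    duration: float = 20.0
    fano: float = 1.83
    n_trajectories: int = 200
    base_seed: int = 20210
    params: dict = field(default_factory=dict)
    outdir: str | None = None

    _KNOWN_FAMILIES = ("isolated", "chain", "minp", "mint")

    def __post_init__(self) -> None:
        bad = set(self.families) - set(self._KNOWN_FAMILIES)
        if bad:
            raise ValueError(f"unknown families {sorted(bad)}")
        if self.scheme not in ("one-step", "two-step"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.method not in ("lna", "ssa"):
            raise ValueError(f"unknown method {self.method!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        inp = d.pop("input", {})
        for src, dst in (("levels", "levels"), ("baseline", "baseline"),
                         ("duration", "duration"), ("fano", "fano")):
            if src in inp:
                d[dst] = inp[src]
        unknown = set(d) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def parameter_set(self) -> ParameterSet:
        return ParameterSet(**self.params)

    def protocol(self) -> InputProtocol:
        return staircase(self.levels, self.duration, self.baseline)

    def input_mechanism(self):
        return calibrate_input(self.fano, self.baseline)


# ---------------------------------------------------------------------------
# per-model computation
# ---------------------------------------------------------------------------


def stationary_plateau_frame(crn: CRNModel, protocol: InputProtocol) -> pd.DataFrame:
    """Plateau statistics from the stationary fast path.

    Relaxation through every plateau is fast relative to the plateau length,
    so end-of-plateau moments coincide with the stationary moments at that
    level; each distinct level is solved once and both phases reported.
    """
    cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    rows = []
    peak = int(np.argmax(protocol.plateaus))
    for i, level in enumerate(protocol.plateaus):
        if level not in cache:
            cache[level] = stationary(crn, level)
        mu, sigma = cache[level]
        phase = "up" if i <= peak else "down"
        for j, name in enumerate(crn.species_names):
            rows.append(
                (crn.model_id, "lna", level, phase, name, mu[j], max(sigma[j, j], 0.0))
            )
    return pd.DataFrame(
        rows, columns=["model_id", "method", "level", "phase", "species", "mean", "var"]
    )


def model_frame(crn: CRNModel, config: RunConfig, seed_offset: int = 0) -> pd.DataFrame:
    protocol = config.protocol()
    if config.method == "lna":
        return stationary_plateau_frame(crn, protocol)
    stats = ensemble(
        crn, protocol, n=config.n_trajectories,
        base_seed=config.base_seed + 1000 * seed_offset,
    )
    return plateau_frame(stats)


def run_catalog(config: RunConfig) -> dict:
    """Sweep the selected families and emit summary/ranking/scatter tables."""
    entries = [
        e for e in full_catalog(config.drop_rule)
        if e.topology.family in config.families
    ]
    params = config.parameter_set()
    mech = config.input_mechanism()
    frames, summaries = [], []
    for k, entry in enumerate(entries):
        crn = build_model(entry, config.scheme, params, mech)
        try:
            frame = model_frame(crn, config, seed_offset=k)
        except Exception as err:
            raise RuntimeError(f"model {entry.model_id} failed: {err}") from err
        frames.append(frame)
        summaries.append(
            summarize(frame, scheme=config.scheme, family=entry.topology.family)
        )
        log.info("ran %s (%s, %s)", entry.model_id, config.scheme, config.method)
    ranking, corr = rank_models(summaries)
    summary_df = _summary_table(summaries)
    sat = saturation_check(pd.concat(frames, ignore_index=True), params.total)
    out = {
        "summary": summary_df,
        "ranking": ranking,
        "scatter": ranking[["model_id", "family", "cv_percent", "slope"]],
        "cv_slope_correlation": corr,
        "saturation_violations": sat,
        "entries": entries,
    }
    if config.outdir:
        _write_outputs(out, config)
    return out


def _summary_table(summaries: list[ModelSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for level, cv in s.cv_percent_output.items():
            rows.append(
                (s.model_id, s.scheme, s.family, s.method, level, cv,
                 s.fano_output[level], s.slope, s.slope_down)
            )
    return pd.DataFrame(
        rows,
        columns=["model_id", "scheme", "family", "method", "level",
                 "cv_percent", "fano", "slope", "slope_down"],
    )


def _write_outputs(out: dict, config: RunConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out["summary"].to_csv(outdir / "summary.csv", index=False)
    out["ranking"].to_csv(outdir / "ranking.csv", index=False)
    out["scatter"].to_csv(outdir / "scatter.csv", index=False)
    catalog_blob = json.dumps(
        [e.to_json_dict() for e in out["entries"]], sort_keys=True
    ).encode()
    meta = {
        "version": __version__,
        "config": asdict(config),
        "catalog_sha256": hashlib.sha256(catalog_blob).hexdigest(),
        "cv_slope_correlation": out["cv_slope_correlation"],
    }
    (outdir / "run_meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# figure-style analyses
# ---------------------------------------------------------------------------


def reproduce(figure_id: str, config: RunConfig | None = None) -> dict:
    """Re-run the computation behind one named comparison.

    Returns ``{"table": DataFrame, "checks": {claim: bool}}``; the checks
    encode each comparison's qualitative claim so deviations are reported,
    never suppressed.
    """
    handlers = {
        "fig2": _repro_isolated_and_chains,
        "fig3": _repro_coupled,
        "fig4": _repro_best_performers,
        "fig5": _repro_schemes,
        "fig6": _repro_gates,
        "fig7": _repro_layers,
        "s5": _repro_schemes,
        "s7": _repro_input_noise,
    }
    if figure_id not in handlers:
        raise ValueError(f"unknown figure id {figure_id!r}; known: {sorted(handlers)}")
    return handlers[figure_id](config or RunConfig())


def _repro_isolated_and_chains(config: RunConfig) -> dict:
    cfg = replace(config, families=["isolated", "chain"])
    out = run_catalog(cfg)
    summary = out["summary"]
    input_cv = {
        lvl: cv_percent(lvl, cfg.fano * lvl) for lvl in set(summary.level)
    }
    iso = summary[summary.family == "isolated"]
    below = bool(
        (iso.cv_percent < iso.level.map(input_cv)).all()
    )
    mono = _all_cv_monotone(summary[summary.family == "isolated"])
    chains = summary[summary.family == "chain"][
        ["model_id", "slope"]
    ].drop_duplicates()
    chain1 = float(chains[chains.model_id == "chain-1"].slope.iloc[0])
    others = chains[chains.model_id != "chain-1"].slope.abs()
    return {
        "table": summary,
        "ranking": out["ranking"],
        "checks": {
            "isolated_output_cv_below_input": below,
            "isolated_cv_decreases_with_input": mono,
            "chain1_transduces_others_near_zero": bool(
                chain1 > 0 and (others < 0.5 * abs(chain1)).all()
            ),
        },
    }


def _repro_coupled(config: RunConfig) -> dict:
    cfg = replace(config, families=["minp", "mint"])
    out = run_catalog(cfg)
    return {
        "table": out["ranking"],
        "checks": {
            "cv_slope_negatively_correlated": out["cv_slope_correlation"] < 0,
        },
    }


def _repro_best_performers(config: RunConfig) -> dict:
    params = config.parameter_set()
    mech = config.input_mechanism()
    summaries = []
    for mid in BEST_PERFORMERS:
        crn = build_model(get_entry(mid, config.drop_rule), config.scheme, params, mech)
        frame = model_frame(crn, config)
        summaries.append(
            summarize(frame, scheme=config.scheme,
                      family=get_entry(mid).topology.family)
        )
    table, _ = rank_models(summaries)
    best_cv = table.model_id.iloc[0]
    best_slope = table.loc[table.slope.idxmax(), "model_id"]
    return {
        "table": table,
        "checks": {
            "best_noise_reducer_is_c1c1_minp_OR": best_cv == "c1c1-minp-OR",
            "best_transducer_is_c4c4_minp_OR": best_slope == "c4c4-minp-OR",
        },
    }


def _repro_schemes(config: RunConfig) -> dict:
    rows = []
    for scheme in ("one-step", "two-step"):
        out = run_catalog(replace(config, scheme=scheme))
        df = out["ranking"].copy()
        df["scheme"] = scheme
        rows.append(df)
    both = pd.concat(rows, ignore_index=True)
    wide = both.pivot_table(
        index=["model_id", "family"], columns="scheme",
        values=["cv_percent", "slope"],
    )
    cv1, cv2 = wide["cv_percent"]["one-step"], wide["cv_percent"]["two-step"]
    s1, s2 = wide["slope"]["one-step"], wide["slope"]["two-step"]
    return {
        "table": both,
        "checks": {
            "two_step_noisier": bool((cv2 >= cv1).all()),
            "two_step_steeper": bool((s2.abs() >= s1.abs()).all()),
        },
        "fraction_two_step_noisier": float((cv2 >= cv1).mean()),
        "fraction_two_step_steeper": float((s2.abs() >= s1.abs()).mean()),
    }


def _gate_pairs(entries: list[CatalogEntry]) -> list[tuple[str, str]]:
    ids = {e.model_id for e in entries}
    pairs = []
    for mid in sorted(ids):
        if mid.endswith("-AND"):
            counterpart = mid[: -len("AND")] + "OR"
            if counterpart in ids:
                pairs.append((counterpart, mid))
    return pairs


def _repro_gates(config: RunConfig) -> dict:
    out = run_catalog(config)
    ranking = out["ranking"].set_index("model_id")
    rows = []
    for or_id, and_id in _gate_pairs(out["entries"]):
        rows.append(
            {
                "or_model": or_id,
                "and_model": and_id,
                "family": ranking.loc[or_id, "family"],
                "cv_or": ranking.loc[or_id, "cv_percent"],
                "cv_and": ranking.loc[and_id, "cv_percent"],
            }
        )
    table = pd.DataFrame(rows)
    table["or_quieter"] = table.cv_or <= table.cv_and
    return {
        "table": table,
        "checks": {"or_gates_quieter_than_and": bool(table.or_quieter.all())},
        "fraction_or_quieter": float(table.or_quieter.mean()),
    }


def _repro_layers(config: RunConfig) -> dict:
    params = config.parameter_set()
    mech = config.input_mechanism()
    rows = []
    for mid in LAYER_PROFILE_MODELS:
        crn = build_model(get_entry(mid), config.scheme, params, mech)
        frame = model_frame(crn, config)
        ref = frame[(frame.level == REFERENCE_INPUT) & (frame.phase == "up")]
        for r in ref.itertuples():
            if r.species == "S" or r.species.endswith("_a"):
                rows.append((mid, r.species, cv_percent(r.mean, r.var)))
    table = pd.DataFrame(rows, columns=["model_id", "species", "cv_percent"])

    def zcv(mid):
        return float(
            table[(table.model_id == mid) & (table.species == OUTPUT_SPECIES)].cv_percent.iloc[0]
        )

    def scv(mid):
        return float(
            table[(table.model_id == mid) & (table.species == "S")].cv_percent.iloc[0]
        )

    good = ["c1-OR", "c1c1-minp-OR", "c1i4-mint-OR"]
    bad = ["c3-OR", "c3c3-minp-OR", "c3i2-mint-OR"]
    mid_layer_best = []
    for mid in bad:
        sub = table[(table.model_id == mid) & (table.species != "S")]
        best = sub.loc[sub.cv_percent.idxmin(), "species"]
        mid_layer_best.append(best.startswith("Y"))
    return {
        "table": table,
        "checks": {
            "good_reducers_attenuate_input": all(zcv(m) < scv(m) for m in good),
            "bad_reducers_quietest_at_middle_layer": all(mid_layer_best),
        },
    }


def _repro_input_noise(config: RunConfig) -> dict:
    params = config.parameter_set()
    rows = []
    for mid in LAYER_PROFILE_MODELS:
        entry = get_entry(mid)
        for scale, fano_val in (("reduced", 1.2), ("default", 1.83), ("increased", 3.0)):
            mech = set_input_noise(scale, config.baseline)
            crn = build_model(entry, config.scheme, params, mech)
            cfg = replace(config, fano=fano_val)
            frame = model_frame(crn, cfg)
            ref = frame[
                (frame.level == REFERENCE_INPUT)
                & (frame.phase == "up")
                & (frame.species == OUTPUT_SPECIES)
            ].iloc[0]
            rows.append((mid, scale, fano_val, cv_percent(ref["mean"], ref["var"])))
    table = pd.DataFrame(rows, columns=["model_id", "scale", "input_fano", "cv_percent"])
    rel_range = (
        table.groupby("model_id").cv_percent.agg(lambda c: (c.max() - c.min()) / c.mean())
    )
    return {
        "table": table,
        "checks": {"output_cv_insensitive_to_input_noise": bool((rel_range <= 0.10).all())},
        "relative_range": rel_range.to_dict(),
    }


def _all_cv_monotone(summary: pd.DataFrame) -> bool:
    ok = True
    for mid, grp in summary.groupby("model_id"):
        cv = grp.sort_values("level").cv_percent.to_numpy()
        ok &= bool((np.diff(cv) < 0).all())
    return ok


# ---------------------------------------------------------------------------
# gate calibration and self-test
# ---------------------------------------------------------------------------


def calibrate_and_factor(
    and_model_id: str,
    at_input: float = 1.0,
    params: ParameterSet | None = None,
    scheme: str = "one-step",
) -> dict:
    """Fit the AND-gate attenuation so both gate variants match at baseline.

    Solves for the ``and_factor`` at which the AND variant's mean output
    equals its OR counterpart's at the given input level, and reports the
    residual mismatch of the default halving convention.  The fitted value
    is logged, not silently adopted.
    """
    from scipy.optimize import brentq

    if not and_model_id.endswith("AND"):
        raise ValueError("pass the AND-gated variant's model id")
    or_id = and_model_id[: and_model_id.rfind("AND")] + "OR"
    params = params or ParameterSet()

    def z_mean(mid, factor):
        p = replace(params, and_factor=factor)
        crn = build_model(get_entry(mid), scheme, p)
        mu, _ = stationary(crn, at_input)
        return mu[crn.species_index(OUTPUT_SPECIES)]

    target = z_mean(or_id, params.and_factor)
    default = z_mean(and_model_id, params.and_factor)

    def gap(f):
        return z_mean(and_model_id, f) - target

    fitted = brentq(gap, 1e-3, 1e3, xtol=1e-6, rtol=1e-8)
    log.info(
        "AND calibration for %s: fitted and_factor=%.4f (default %.2f gives %.3g vs OR %.3g)",
        and_model_id, fitted, params.and_factor, default, target,
    )
    return {
        "and_model": and_model_id,
        "or_model": or_id,
        "fitted_and_factor": float(fitted),
        "default_and_factor": params.and_factor,
        "mean_with_default": float(default),
        "mean_or_variant": float(target),
    }


def selftest() -> dict:
    """Fast oracle suite: enumeration counts, closed forms, engine agreement."""
    from .catalog import enumerate_chains, enumerate_isolated, enumerate_mint, enumerate_minp
    from .crn import input_only_model, unregulated_node_model, conservation_laws, stoichiometry
    from .ssa import simulate

    report: dict[str, bool] = {}
    report["isolated_count_12"] = len(enumerate_isolated()) == 12
    report["chain_count_4"] = len(enumerate_chains()) == 4
    report["mint_count_26"] = len(enumerate_mint()) == 26
    report["minp_naive_count_42"] = len(enumerate_minp("none")) == 42

    m = input_only_model()
    mu, sig = stationary(m, 6.0)
    report["input_fano_1.83"] = abs(sig[0, 0] / mu[0] - 1.83) < 1e-9

    node = unregulated_node_model()
    mu, sig = stationary(node, 1.0)
    ia = node.species_index("N_a")
    report["binomial_node_moments"] = (
        abs(mu[ia] - 10.0) < 1e-8 and abs(sig[ia, ia] - 60 * (1 / 6) * (5 / 6)) < 1e-6
    )

    crn = build_model("c1-OR")
    S = stoichiometry(crn)
    names = crn.species_names
    ok = True
    for forms, _ in conservation_laws(crn):
        v = np.zeros(len(names))
        for f in forms:
            v[names.index(f)] = 1.0
        ok &= bool((v @ S == 0).all())
    report["conservation_exact"] = ok

    proto = staircase()
    t1 = simulate(crn, proto, seed=1, sample_times=np.linspace(0, 40, 81))
    t2 = simulate(crn, proto, seed=1, sample_times=np.linspace(0, 40, 81))
    report["ssa_seed_reproducible"] = bool(np.array_equal(t1.states, t2.states))

    report["all_passed"] = all(report.values())
    return report
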