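"""Pipeline runners connecting file I/O to the fitting models.

Each runner takes a :class:`bindkin.io.RunConfig`, loads and validates
the inputs, runs the matching model and assembles a
:class:`bindkin.io.ResultBundle` whose derived quantities (nH, TdS,
k_GE/k_EG, Rex tables) are recomputed from the fitted parameters.
"""

from __future__ import annotations

import pandas as pd

from . import io as bio
from .itc import ITCModel, hill_coefficient, stepwise_entropy, default_protocol
from .stoppedflow import MechanismModel, KineticScheme
from .titration import TitrationModel, classify_perturbations
from .cpmg import (
    DispersionModel, GlobalDispersionModel, rex_estimate, exchange_rates,
    carver_richards_r2eff, REX_SCREEN_HZ,
)


def run_itc(config) -> "bio.ResultBundle":
    iso = bio.read_isotherm(config.data)
    proto_path = config.options.get("protocol")
    protocol = bio.read_protocol_config(proto_path) if proto_path else default_protocol()
    model = ITCModel(iso, protocol, exclude_first=bool(config.options.get("exclude_first", False)))
    tables = {}
    if config.kind == "itc_bayes":
        res = model.fit_bayes(
            n_samples=int(config.options.get("n_samples", 10000)),
            burn_in=int(config.options.get("burn_in", 1000)),
            seed=config.seed,
        )
        m, s = res.posterior_mean(), res.posterior_sd()
        params = {k: {"mean": m[k], "sd": s[k]} for k in m}
        kd1, kd2, dh1, dh2 = m["kd1"], m["kd2"], m["dh1"], m["dh2"]
        tables["posterior_samples"] = pd.DataFrame(
            res.samples, columns=["kd1_M", "kd2_M", "dh1_kcal_per_mol",
                                  "dh2_kcal_per_mol", "dilution_heat_kcal_per_mol",
                                  "noise_scale_kcal_per_mol"])
        tables["kd_scatter"] = res.kd_scatter()
        diag = {"acceptance_fraction": res.acceptance_fraction,
                "split_chain_ratio": list(res.split_chain_ratio),
                "wide_parameters": res.wide_parameters,
                "warnings": list(res.warnings)}
    else:
        res = model.fit()
        p = res.params
        kd1, kd2, dh1, dh2 = p.kd1, p.kd2, p.dh1, p.dh2
        params = {"kd1_M": kd1, "kd2_M": kd2, "dh1_kcal_per_mol": dh1,
                  "dh2_kcal_per_mol": dh2, "dilution_heat_kcal_per_mol": res.dilution_heat}
        diag = {"rss": res.rss, "kd_unidentifiable": res.kd_unidentifiable}
    t = protocol.temperature
    derived = {
        "nH": hill_coefficient(kd1, kd2),
        "tds1_kcal_per_mol": stepwise_entropy(dh1, kd1, t),
        "tds2_kcal_per_mol": stepwise_entropy(dh2, kd2, t),
        "diagnostics": diag,
    }
    tables["parameters"] = res.summary()
    return bio.ResultBundle(kind=config.kind, parameters=params, derived=derived,
                            tables=tables, seed=config.seed)


def run_mechanism(config) -> "bio.ResultBundle":
    observed = bio.read_observed_rates(config.data)
    init = KineticScheme(**config.options["init"])
    fixed = frozenset(config.options.get("fixed", ("k1", "k_1")))
    res = MechanismModel(observed).fit(init=init, fixed=fixed)
    params = {n: getattr(res.scheme, n) for n in
              ("k1", "k_1", "k2", "k_2", "k3", "k_3", "k4", "k_4")}
    derived = {"rss": res.rss, "unidentifiable": res.unidentifiable,
               "stderr": res.stderr, "fixed": sorted(res.fixed)}
    tables = {"rate_constants": res.summary(), "fitted_rates": res.predicted.to_frame()}
    return bio.ResultBundle(kind=config.kind, parameters=params, derived=derived,
                            tables=tables, seed=config.seed)


def run_pka(config) -> "bio.ResultBundle":
    curves = bio.read_titration(config.data)
    fits = [TitrationModel(c).fit() for c in curves]
    table = pd.concat([f.summary() for f in fits], ignore_index=True)
    params = {f.residue: {"pKa": f.pka, "pKa_err": f.pka_err} for f in fits}
    return bio.ResultBundle(kind="pka", parameters=params,
                            derived={"n_residues": len(fits)},
                            tables={"pka_fits": table}, seed=config.seed)


def run_shifts(config) -> "bio.ResultBundle":
    perts = bio.read_perturbations(config.data)
    w1 = float(config.options.get("w1", 0.154))
    tiered = classify_perturbations(perts, w1=w1)
    table = pd.DataFrame(
        [(p.residue, p.d_hn, p.d_n, p.combined, p.tier) for p in tiered],
        columns=["residue", "dHN_ppm", "dN_ppm", "combined_ppm", "tier"])
    return bio.ResultBundle(kind="shifts", parameters={"w1": w1},
                            derived={"n_residues": len(tiered)},
                            tables={"perturbations": table}, seed=config.seed)


def run_cpmg(config) -> "bio.ResultBundle":
    profiles = bio.read_dispersion(config.data)
    screen = float(config.options.get("rex_screen", REX_SCREEN_HZ))
    rex_table = pd.DataFrame(
        [(p.residue, rex_estimate(p), rex_estimate(p) > screen) for p in profiles],
        columns=["residue", "rex_s", "kept"])
    kept = [p for p in profiles if rex_estimate(p) > screen]
    tables = {"rex_screen": rex_table}
    if config.kind == "cpmg_individual":
        fits = [DispersionModel(p).fit(seed=config.seed) for p in kept]
        tables["exchange"] = pd.concat([f.summary() for f in fits], ignore_index=True)
        params = {f.residue: {"kex_s": f.exchange.kex, "pE": f.exchange.p_e} for f in fits}
        derived = {"kGE_s": {f.residue: f.k_ge for f in fits},
                   "kEG_s": {f.residue: f.k_eg for f in fits}}
    else:
        clusters = config.options.get("clusters")
        if clusters is None:
            clusters = {"all": [p.residue for p in kept]}
        params, derived, blocks = {}, {}, []
        for name, members in clusters.items():
            sub = [p for p in kept if p.residue in set(members)]
            if not sub:
                continue
            res = GlobalDispersionModel(sub).fit()
            kge, keg = exchange_rates(res.exchange.kex, res.exchange.p_e)
            params[name] = {"kex_s": res.exchange.kex, "pE": res.exchange.p_e,
                            "kex_err": res.stderr["kex"], "pE_err": res.stderr["p_e"]}
            derived[name] = {"kGE_s": kge, "kEG_s": keg, "chi2": res.chi2}
            blk = res.summary()
            blk.insert(0, "cluster", name)
            blocks.append(blk)
        if blocks:
            tables["exchange"] = pd.concat(blocks, ignore_index=True)
        derived["n_profiles"] = len(kept)
    return bio.ResultBundle(kind=config.kind, parameters=params, derived=derived,
                            tables=tables, seed=config.seed)
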