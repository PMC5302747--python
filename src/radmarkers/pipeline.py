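"""End-to-end orchestration: simulate -> (preprocess) -> screen -> select
-> evaluate, for every declared group comparison.

The default study reproduces the design of the emulated experiment: four
dose groups on two sampling days, and seven comparisons -- sham vs.
irradiated on day 3, day 7 and both days pooled (triage), and the two
severity contrasts 20 vs. 40+80 Gy and 20+40 vs. 80 Gy on each day
(prognosis).  All randomness derives from one master seed through named
substreams, so a rerun with an identical configuration reproduces
identical result files.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .containers import ConfigurationError, LabeledMatrix, meta_frame
from .evaluate import evaluate_panel
from .io import (
    write_eval_report,
    write_matrix_tsv,
    write_peak_matrix_tsv,
    write_selection_result,
    write_stats_table,
)
from .seldi import ClusterParams, spectra_to_peak_matrix
from .selection import (
    PlsSelectParams,
    RfSelectParams,
    child_seed,
    plsda_stability_select,
    rf_stability_select,
)
from .simulate import (
    DigeSimConfig,
    MarkerSpec,
    SeldiSimConfig,
    generate_dige_dataset,
    generate_seldi_spectra,
    table1_like_markers,
)
from .univariate import Comparison, comparison_stats, select_candidates

__all__ = [
    "StudyConfig",
    "RunManifest",
    "default_comparisons",
    "default_study_config",
    "run_pipeline",
]


def default_comparisons(days: tuple[int, ...] = (3, 7)) -> list[Comparison]:
    """The seven study contrasts: triage per day and pooled, plus the two
    severity splits per day."""
    comps = []
    for d in days:
        comps.append(
            Comparison(
                f"ctrl_vs_ir_d{d}",
                frozenset({(0.0, d)}),
                frozenset({(20.0, d), (40.0, d), (80.0, d)}),
            )
        )
    comps.append(
        Comparison(
            "ctrl_vs_ir_d3d7",
            frozenset({(0.0, d) for d in days}),
            frozenset({(dose, d) for d in days for dose in (20.0, 40.0, 80.0)}),
        )
    )
    for d in days:
        comps.append(
            Comparison(
                f"20_vs_4080_d{d}",
                frozenset({(20.0, d)}),
                frozenset({(40.0, d), (80.0, d)}),
            )
        )
        comps.append(
            Comparison(
                f"2040_vs_80_d{d}",
                frozenset({(20.0, d), (40.0, d)}),
                frozenset({(80.0, d)}),
            )
        )
    return comps


@dataclass
class StudyConfig:
    platform: str = "dige"  # or "seldi"
    days: tuple[int, ...] = (3, 7)
    dige: DigeSimConfig = field(default_factory=DigeSimConfig)
    seldi: SeldiSimConfig = field(default_factory=SeldiSimConfig)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    comparisons: list[Comparison] = field(default_factory=default_comparisons)
    selection_method: str = "plsda"  # or "rf"
    selection_scope: str = "train"  # or "all" (the original workflow's protocol)
    pls_params: PlsSelectParams = field(default_factory=PlsSelectParams)
    rf_params: RfSelectParams = field(default_factory=RfSelectParams)
    alpha: float = 0.05
    n_perm: int = 9999
    train_frac: float = 0.70
    cv_folds: int = 5
    master_seed: int = 0

    def validate(self) -> None:
        if self.platform not in ("dige", "seldi"):
            raise ConfigurationError(f"unknown platform {self.platform!r}")
        if self.selection_method not in ("plsda", "rf"):
            raise ConfigurationError(f"unknown selection_method {self.selection_method!r}")
        if self.selection_scope not in ("train", "all"):
            raise ConfigurationError(f"unknown selection_scope {self.selection_scope!r}")
        declared_doses = set(
            float(d) for d in (self.dige.doses if self.platform == "dige" else self.seldi.doses)
        )
        declared = {(d, int(t)) for d in declared_doses for t in self.days}
        for comp in self.comparisons:
            undeclared = (comp.left | comp.right) - declared
            if undeclared:
                raise ConfigurationError(
                    f"comparison {comp.name!r} references undeclared design "
                    f"cell(s) {sorted(undeclared)}"
                )
        (self.dige if self.platform == "dige" else self.seldi).validate()

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "platform": self.platform,
            "days": list(self.days),
            "dige": _sim_dict(self.dige),
            "seldi": _sim_dict(self.seldi),
            "cluster": asdict(self.cluster),
            "comparisons": [
                {"name": c.name, "left": sorted(map(list, c.left)),
                 "right": sorted(map(list, c.right))}
                for c in self.comparisons
            ],
            "selection_method": self.selection_method,
            "selection_scope": self.selection_scope,
            "pls_params": asdict(self.pls_params),
            "rf_params": asdict(self.rf_params),
            "alpha": self.alpha,
            "n_perm": self.n_perm,
            "train_frac": self.train_frac,
            "cv_folds": self.cv_folds,
            "master_seed": self.master_seed,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        cfg = cls()
        if "platform" in d:
            cfg.platform = d["platform"]
        if "days" in d:
            cfg.days = tuple(int(x) for x in d["days"])
        if "dige" in d:
            dd = dict(d["dige"])
            markers = [MarkerSpec(**mk) for mk in dd.pop("markers", [])]
            cfg.dige = DigeSimConfig(markers=markers, **dd)
        if "seldi" in d:
            from .simulate import PeakSpec

            sd = dict(d["seldi"])
            peaks = sd.pop("true_peaks", None)
            if peaks is not None:
                peaks = [PeakSpec(**pk) for pk in peaks]
            cfg.seldi = SeldiSimConfig(true_peaks=peaks, **sd)
        if "cluster" in d:
            cfg.cluster = ClusterParams(**d["cluster"])
        if "comparisons" in d:
            cfg.comparisons = [
                Comparison(
                    c["name"],
                    frozenset((float(a), int(b)) for a, b in c["left"]),
                    frozenset((float(a), int(b)) for a, b in c["right"]),
                )
                for c in d["comparisons"]
            ]
        if "pls_params" in d:
            cfg.pls_params = PlsSelectParams(**d["pls_params"])
        if "rf_params" in d:
            cfg.rf_params = RfSelectParams(**d["rf_params"])
        for key in ("selection_method", "selection_scope", "alpha", "n_perm",
                    "train_frac", "cv_folds", "master_seed"):
            if key in d:
                setattr(cfg, key, d[key])
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        from .io import load_yaml

        return cls.from_dict(load_yaml(path))


def _sim_dict(cfg) -> dict:
    d = asdict(cfg)
    if "markers" in d:
        d["markers"] = [asdict(mk) for mk in cfg.markers]
    if d.get("true_peaks") is not None:
        d["true_peaks"] = [asdict(pk) for pk in cfg.true_peaks]
    d["doses"] = list(d["doses"])
    return d


def default_study_config(master_seed: int = 0) -> StudyConfig:
    """The planted-marker gel study used by the worked example: the full
    941-feature design with a Table-1-like marker panel."""
    cfg = StudyConfig(master_seed=master_seed)
    cfg.dige = DigeSimConfig(markers=table1_like_markers())
    return cfg


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    stage_seeds: dict
    outputs: dict
    wall_times: dict
    funnel: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _config_hash(config: StudyConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _simulate_platform(config: StudyConfig, sim_seed: int):
    """Returns (LabeledMatrix for statistics, extra outputs dict)."""
    if config.platform == "dige":
        parts = []
        for day in config.days:
            day_cfg = DigeSimConfig(**{**asdict_shallow(config.dige), "seed": sim_seed})
            parts.append(generate_dige_dataset(day_cfg, day))
        values = np.vstack([p.values for p in parts])
        meta = meta_frame([])
        import pandas as pd

        meta = pd.concat([p.meta for p in parts], ignore_index=True)
        return LabeledMatrix(values, parts[0].feature_ids, meta), {}
    # SELDI: simulate spectra per day, preprocess to a peak matrix
    mats, extras = [], {}
    for day in config.days:
        s_cfg = SeldiSimConfig(**{**asdict_shallow(config.seldi), "seed": sim_seed, "day": day})
        spectra, truth = generate_seldi_spectra(s_cfg)
        pm = spectra_to_peak_matrix(spectra, config.cluster)
        extras[f"peak_matrix_d{day}"] = pm
        vals = pm.values.T.copy()
        positive = vals[vals > 0]
        floor = 0.5 * positive.min() if positive.size else 1e-6
        vals[vals <= 0] = floor  # absent peaks: half the smallest observed intensity
        fids = [f"mz{m:.1f}" for m in pm.cluster_mz]
        mats.append(LabeledMatrix(vals, fids, spectra.meta.copy()))
    if len(mats) > 1:
        # peak sets differ between days; restrict to one day per comparison
        extras["per_day_matrices"] = mats
    return mats[0], extras


def asdict_shallow(cfg) -> dict:
    """dataclass -> dict, keeping nested marker/peak objects intact."""
    d = {f: getattr(cfg, f) for f in cfg.__dataclass_fields__}
    return d


def run_pipeline(config: StudyConfig, outdir: str | Path) -> RunManifest:
    """Execute every stage for every declared comparison.

    Per comparison, samples are split 70/30 (stratified); screening and
    (by default) stability selection see only the learning rows, and the
    evaluation report scores the refit panel on the held-out rows.  With
    ``selection_scope='all'`` the stability selector instead sees every
    sample of the comparison -- the original workflow's protocol, which
    buys selection power at the price of optimistically biased held-out
    metrics.  A full-data screening table is additionally written for the
    candidate-funnel audit (it feeds no classifier).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    wall: dict[str, float] = {}
    outputs: dict[str, str] = {}

    seeds = {
        "simulate": child_seed(config.master_seed, 10),
        "univariate": child_seed(config.master_seed, 11),
        "split": child_seed(config.master_seed, 12),
        "selection": child_seed(config.master_seed, 13),
    }

    m, extras = _simulate_platform(config, seeds["simulate"])
    outputs["matrix"] = str(write_matrix_tsv(m, outdir / "matrix.tsv"))
    for key, pm in extras.items():
        if key.startswith("peak_matrix"):
            outputs[key] = str(write_peak_matrix_tsv(pm, outdir / f"{key}.tsv"))
    wall["simulate"] = time.perf_counter() - t0

    from sklearn.model_selection import train_test_split

    funnel: dict[str, dict] = {"n_features": m.n_features, "comparisons": {}}
    full_tables = {}
    for ci, comp in enumerate(config.comparisons):
        tc = time.perf_counter()
        cdir = outdir / comp.name
        cdir.mkdir(exist_ok=True)
        mask, labels = comp.labels(m)
        sub = m.subset_samples(mask)

        idx = np.arange(sub.n_samples)
        tr, te = train_test_split(
            idx, train_size=config.train_frac, stratify=labels,
            random_state=child_seed(seeds["split"], ci),
        )
        tr.sort(); te.sort()
        m_train, m_test = sub.subset_samples(tr), sub.subset_samples(te)
        y_train, y_test = labels[tr], labels[te]

        table = comparison_stats(
            m_train, comp, n_perm=config.n_perm,
            seed=child_seed(seeds["univariate"], ci),
        )
        outputs[f"{comp.name}/stats"] = str(write_stats_table(table, cdir / "stats.tsv"))
        full_tables[comp.name] = comparison_stats(
            m, comp, n_perm=config.n_perm, seed=child_seed(seeds["univariate"], ci, 1)
        )

        m_sel = sub if config.selection_scope == "all" else m_train
        y_sel = labels if config.selection_scope == "all" else y_train
        if config.selection_method == "plsda":
            params = PlsSelectParams(**{**asdict(config.pls_params),
                                        "seed": child_seed(seeds["selection"], ci)})
            sel = plsda_stability_select(m_sel, y_sel, params)
            method = "lda"
        else:
            params = RfSelectParams(**{**asdict(config.rf_params),
                                       "seed": child_seed(seeds["selection"], ci)})
            sel = rf_stability_select(m_sel, y_sel, params)
            method = "logistic"
        outputs[f"{comp.name}/selection"] = str(
            write_selection_result(sel, cdir / "selection.json")
        )

        lookup = {f: j for j, f in enumerate(m.feature_ids)}
        cand_idx = [lookup[f] for f in sel.selected]
        report = evaluate_panel(
            m_train.log_values(), y_train, m_test.log_values(), y_test,
            cand_idx, method=method, feature_ids=m.feature_ids,
            cv_folds=config.cv_folds,
        )
        outputs[f"{comp.name}/eval"] = str(write_eval_report(report, cdir / "eval.json"))
        funnel["comparisons"][comp.name] = {
            "n_train": int(len(tr)),
            "n_test": int(len(te)),
            "n_selected": len(sel.selected),
            "panel": report.panel.variables,
            "test_auc": report.roc["test"].auc,
        }
        wall[comp.name] = time.perf_counter() - tc

    union, counts = select_candidates(full_tables, alpha=config.alpha)
    funnel["candidate_union_size"] = len(union)
    funnel["candidates_per_comparison"] = counts

    manifest = RunManifest(
        _config_hash(config), config.master_seed, seeds, outputs, wall, funnel
    )
    (outdir / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=1, sort_keys=True)
    )
    return manifest
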