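"""Config-driven end-to-end runner: simulate → link → cohort → classify →
comorbidity → summarize, with a manifest for reproducibility audits.

Every stage writes plain CSV/JSON artifacts into the output directory and
records its row counts in ``manifest.json`` together with the seed and a
hash of the configuration, so two runs with one seed are byte-identical and
a changed configuration is detectable.  Stages can be re-run individually;
a stage whose inputs are neither in memory nor on disk fails with an
explicit dependency error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .admin_rules import AdminRuleConfig, apply_admin_definition, default_admin_config
from .bundle import read_bundle, write_bundle
from .cohort import build_cohort
from .comorbidity import classify_bundle, default_conditions
from .descriptives import assign_groups, group_compare, summarize
from .emr_rules import CaseDefinition, apply_emr_definition, default_definition
from .linkage import Crosswalk, link_deterministic
from .simulate import SimConfig, generate

__all__ = ["PipelineConfig", "PipelineDependencyError", "run_pipeline"]

STAGES = ("simulate", "link", "cohort", "classify", "comorbidity", "summarize")


class PipelineDependencyError(RuntimeError):
    def __init__(self, stage: str, needs: str):
        super().__init__(f"stage {stage!r} requires {needs}, which is neither in "
                         f"memory nor present in the output directory")


@dataclass
class PipelineConfig:
    out_dir: str
    index_year: int = 2014
    seed: int = 0
    n_persons: int = 5000
    stages: tuple = STAGES
    emr_dir: str | None = None       # pre-existing bundles when not simulating
    admin_dir: str | None = None
    emr_rules_path: str | None = None
    admin_rules_path: str | None = None
    salt: str = "frailscan"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["stages"] = tuple(raw.get("stages", STAGES))
        return cls(**raw)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir")  # analysis fingerprint, not artifact location
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_calls(calls: pd.DataFrame, path: Path) -> None:
    df = calls.copy()
    df["evidence"] = [json.dumps([[a, None if d is None else str(d), s]
                                  for a, d, s in ev]) for ev in df["evidence"]]
    df.to_csv(path, index=False, lineterminator="\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the requested stages in canonical order; returns the artifact dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    iy = config.index_year
    stages = [s for s in STAGES if s in config.stages]
    counts: dict[str, int] = {}
    state: dict = {}

    def need_bundles(stage: str):
        if "emr" in state:
            return
        emr_dir = config.emr_dir or (out / "emr")
        admin_dir = config.admin_dir or (out / "admin")
        if not Path(emr_dir).exists() or not Path(admin_dir).exists():
            raise PipelineDependencyError(stage, "simulated or provided bundles")
        state["emr"] = read_bundle(emr_dir, "emr")
        state["admin"] = read_bundle(admin_dir, "admin")

    def need(stage: str, key: str, loader):
        if key in state:
            return
        try:
            state[key] = loader()
        except FileNotFoundError as exc:
            raise PipelineDependencyError(stage, key) from exc

    for stage in stages:
        if stage == "simulate":
            sim = SimConfig(n_persons=config.n_persons, index_year=iy, seed=config.seed)
            emr, admin, truth = generate(sim)
            write_bundle(emr, out / "emr")
            write_bundle(admin, out / "admin")
            tr = truth.copy()
            tr.to_csv(out / "truth.csv", index=False, lineterminator="\n")
            state.update(emr=emr, admin=admin, truth=truth)
            counts["persons_emr"] = len(emr.persons)
            counts["persons_admin"] = len(admin.persons)

        elif stage == "link":
            need_bundles(stage)
            xw = link_deterministic(state["emr"], state["admin"], salt=config.salt)
            xw.table.to_csv(out / "crosswalk.csv", index=False, lineterminator="\n")
            state["crosswalk"] = xw
            counts["links"] = len(xw.table)

        elif stage == "cohort":
            need_bundles(stage)
            need(stage, "crosswalk", lambda: Crosswalk(
                table=pd.read_csv(out / "crosswalk.csv", dtype=str),
                linkage_rate=float("nan"), unlinked_emr=[], unlinked_admin=[]))
            cohort = build_cohort(state["emr"], state["admin"], state["crosswalk"], iy)
            cohort.to_csv(out / "cohort.csv", index=False, lineterminator="\n")
            state["cohort"] = cohort
            counts["cohort_rows"] = len(cohort)
            counts["cohort_included"] = int(cohort["included"].sum())

        elif stage == "classify":
            need_bundles(stage)
            need(stage, "cohort", lambda: _read_cohort(out / "cohort.csv"))
            emr_def = (CaseDefinition.from_json(config.emr_rules_path)
                       if config.emr_rules_path else default_definition())
            admin_cfg = (AdminRuleConfig.from_yaml(config.admin_rules_path)
                         if config.admin_rules_path else default_admin_config())
            emr_calls = apply_emr_definition(emr_def, state["emr"], state["cohort"], iy)
            admin_calls = apply_admin_definition(state["admin"], state["cohort"], iy,
                                                 admin_cfg)
            _write_calls(emr_calls, out / "emr_calls.csv")
            _write_calls(admin_calls, out / "admin_calls.csv")
            state.update(emr_calls=emr_calls, admin_calls=admin_calls)
            counts["emr_frail"] = int(emr_calls["frail"].sum())
            counts["admin_frail"] = int(admin_calls["frail"].sum())

        elif stage == "comorbidity":
            need_bundles(stage)
            need(stage, "cohort", lambda: _read_cohort(out / "cohort.csv"))
            cohort = state["cohort"]
            inc = cohort[cohort["included"]]
            conditions = default_conditions()
            emr_flags = classify_bundle(state["emr"], inc["emr_person_id"], iy, conditions)
            admin_flags = classify_bundle(state["admin"], inc["admin_person_id"], iy,
                                          conditions)
            emr_flags.astype(int).to_csv(out / "conditions_emr.csv", lineterminator="\n")
            admin_flags.astype(int).to_csv(out / "conditions_admin.csv",
                                           lineterminator="\n")
            state.update(emr_flags=emr_flags, admin_flags=admin_flags)
            counts["conditions_emr_rows"] = len(emr_flags)
            counts["conditions_admin_rows"] = len(admin_flags)

        elif stage == "summarize":
            need_bundles(stage)
            for key, loader in (
                ("cohort", lambda: _read_cohort(out / "cohort.csv")),
                ("emr_calls", lambda: _read_calls(out / "emr_calls.csv")),
                ("admin_calls", lambda: _read_calls(out / "admin_calls.csv")),
                ("emr_flags", lambda: pd.read_csv(out / "conditions_emr.csv",
                                                  index_col=0).astype(bool)),
                ("admin_flags", lambda: pd.read_csv(out / "conditions_admin.csv",
                                                    index_col=0).astype(bool)),
            ):
                need(stage, key, loader)
            groups = assign_groups(state["emr_calls"], state["admin_calls"],
                                   state["cohort"])
            table = summarize(groups, state["emr"], state["admin"], state["cohort"],
                              state["emr_flags"], state["admin_flags"], iy)
            groups.to_csv(out / "groups.csv", index=False, lineterminator="\n")
            table.group_sizes.rename("n").to_csv(out / "group_sizes.csv",
                                                 lineterminator="\n")
            table.categorical.to_csv(out / "characteristics.csv", index=False,
                                     lineterminator="\n")
            table.continuous.to_csv(out / "vitals.csv", index=False, lineterminator="\n")
            table.utilization.to_csv(out / "utilization.csv", index=False,
                                     lineterminator="\n")
            comparison = group_compare(table, "emr_only", "admin_only")
            comparison.to_csv(out / "comparison.csv", index=False, lineterminator="\n")
            state["summary"] = table
            counts["groups_rows"] = len(groups)

    manifest = {
        "frailscan_version": __version__,
        "seed": config.seed,
        "index_year": iy,
        "config_hash": config.config_hash(),
        "stages_run": stages,
        "row_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True)
                                       + "\n")
    return out


def _read_cohort(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"emr_person_id": str, "admin_person_id": str,
                                  "scrambled_id": str}, keep_default_na=False)
    df["included"] = df["included"].astype(str).str.lower() == "true"
    df["age_on_jan1"] = df["age_on_jan1"].astype(int)
    df["coverage_fraction"] = df["coverage_fraction"].astype(float)
    return df


def _read_calls(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["frail"] = df["frail"].str.lower() == "true"
    df["evidence"] = [
        [(a, d, s) for a, d, s in json.loads(ev)] for ev in df["evidence"]
    ]
    return df
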