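"""End-to-end orchestration and the fixture reproduction report.

:func:`run_report` re-derives the study's printed summary statistics from
the packaged per-patient tables — group naming means by category, the
close/distant word-picture matching effects, the lesion-volume comparison
— and, when damage profiles and effect scores are supplied, the ROI x
effect Spearman correlation tables.  Every number is written alongside
its test metadata in stable-schema TSVs, and the configuration (with
seed and a content hash) is echoed into the output directory for
provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .behavioural_analysis import accuracy_summary, results_table, t_test
from .damage_effect_mapping import damage_effect_table
from .synthetic_data import load_fixture

logger = logging.getLogger("confusel")

__all__ = ["RunConfig", "run_report"]

NAMING_MEASURES = ["all", "living", "nonliving", "animal", "tool", "fruit_veg", "vehicle"]
WPM_MEASURES = [
    "close", "distant", "living_close", "living_distant",
    "nonliving_close", "nonliving_distant",
]
CATEGORY_PAIRS = [
    ("animal", "tool"), ("animal", "vehicle"), ("fruit_veg", "vehicle"),
    ("fruit_veg", "tool"), ("tool", "vehicle"),
]


@dataclass
class RunConfig:
    """Configuration for a report run (serialised into the output)."""

    out_dir: str
    seed: int = 0
    alpha: float = 0.05
    min_shared: int = 3
    binarize_threshold: float = 0.5
    tail_followup: str = "one"  # the study's a-priori one-tailed follow-ups
    control_roi: str | None = None
    profiles_path: str | None = None
    effects_path: str | None = None
    effect_directions: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


def _patient_long(table: pd.DataFrame, measures: list[str]) -> pd.DataFrame:
    """Melt per-patient percentage rows to participant-level proportions."""
    pat = table[table["row_type"] == "patient"]
    long = pat.melt(
        id_vars=["patient", "group"], value_vars=measures,
        var_name="measure", value_name="pct",
    )
    long["prop"] = long["pct"] / 100.0
    return long.rename(columns={"patient": "participant"})


def _summary_with_printed_controls(
    table: pd.DataFrame, measures: list[str]
) -> pd.DataFrame:
    """Group x measure mean/SEM: patient groups recomputed from per-patient
    rows, the control group taken from the printed summary rows."""
    long = _patient_long(table, measures)
    summary = accuracy_summary(long, by=["group", "measure"], value="prop")
    printed = table[(table["row_type"] != "patient") & (table["group"] == "control")]
    ctrl_rows = []
    for m in measures:
        mean = float(printed.loc[printed["row_type"] == "mean", m].iloc[0])
        sem = float(printed.loc[printed["row_type"] == "sem", m].iloc[0])
        ctrl_rows.append(
            {"group": "control", "measure": m, "mean_pct": mean, "sem_pct": sem,
             "n": pd.NA, "empty": False, "source": "printed"}
        )
    summary["source"] = "recomputed"
    out = pd.concat([summary, pd.DataFrame(ctrl_rows)], ignore_index=True)
    out["measure"] = pd.Categorical(out["measure"], categories=measures, ordered=True)
    return out.sort_values(["group", "measure"]).reset_index(drop=True)


def naming_report(tail: str = "two") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Naming summary and the category follow-up t tests for the
    vATL-damaged group (paired, on unrounded per-patient proportions)."""
    table = load_fixture("table4_naming")
    summary = _summary_with_printed_controls(table, NAMING_MEASURES)
    pat = table[(table["row_type"] == "patient") & (table["group"] == "vATL-damaged")]
    tests = []
    res = t_test(pat["living"], pat["nonliving"], paired=True, tail=tail, direction="less")
    res.effect = "living vs nonliving (vATL-damaged, paired)"
    tests.append(res)
    for a, b in CATEGORY_PAIRS:
        r = t_test(pat[a], pat[b], paired=True, tail=tail, direction="less")
        r.effect = f"{a} vs {b} (vATL-damaged, paired)"
        tests.append(r)
    return summary, results_table(tests)


def wpm_report(tail: str = "two") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Word-picture matching summary and close/distant follow-up tests."""
    table = load_fixture("table8_wpm")
    summary = _summary_with_printed_controls(table, WPM_MEASURES)
    tests = []
    for grp in ("vATL-damaged", "vATL-intact"):
        pat = table[(table["row_type"] == "patient") & (table["group"] == grp)]
        r = t_test(pat["close"], pat["distant"], paired=True, tail=tail, direction="less")
        r.effect = f"close vs distant ({grp}, paired)"
        tests.append(r)
    dmg = table[(table["row_type"] == "patient") & (table["group"] == "vATL-damaged")]
    inta = table[(table["row_type"] == "patient") & (table["group"] == "vATL-intact")]
    r = t_test(
        dmg["close"] - dmg["distant"], inta["close"] - inta["distant"],
        welch=True, tail=tail, direction="less",
    )
    r.effect = "distance effect: vATL-damaged vs vATL-intact (Welch)"
    tests.append(r)
    return summary, results_table(tests)


def volumes_report(tail: str = "two") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group lesion-volume means and the pooled two-sample t test."""
    table = load_fixture("table1_volumes")
    g = table.groupby("group")["lesion_volume_cm3"]
    summary = g.agg(mean="mean", sd="std", n="count").reset_index()
    dmg = table.loc[table["group"] == "vATL-damaged", "lesion_volume_cm3"]
    inta = table.loc[table["group"] == "vATL-intact", "lesion_volume_cm3"]
    res = t_test(dmg, inta, tail=tail)
    res.effect = "lesion volume: vATL-damaged vs vATL-intact (pooled)"
    return summary, results_table([res])


def run_report(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Produce the fixture reproduction report into ``cfg.out_dir``.

    Emits TSVs for the naming summary and follow-up tests (per-category
    group means), the word-picture matching summary and distance-effect
    tests, and the lesion-volume comparison; when ``profiles_path`` and
    ``effects_path`` are set, also the damage x effect correlation table.
    Partial inputs run the available stages and log the skipped ones.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle: dict[str, pd.DataFrame] = {}
    bundle["naming_summary"], bundle["naming_tests"] = naming_report()
    bundle["wpm_summary"], bundle["wpm_tests"] = wpm_report()
    bundle["volumes_summary"], bundle["volumes_tests"] = volumes_report()

    if cfg.profiles_path and cfg.effects_path:
        profiles = pd.read_csv(cfg.profiles_path, sep="\t", index_col="patient")
        effects = pd.read_csv(cfg.effects_path, sep="\t", index_col="patient")
        directions = cfg.effect_directions or "negative"
        bundle["damage_effects"] = damage_effect_table(
            profiles, effects, directions=directions, tail=cfg.tail_followup,
            control=cfg.control_roi, alpha=cfg.alpha,
        )
    else:
        logger.info("run_report: no damage profiles/effects supplied; skipping damage mapping")

    for name, df in bundle.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False)

    config_text = cfg.to_yaml()
    (out / "config.yaml").write_text(config_text)
    provenance = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "seed": cfg.seed,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "stages": sorted(bundle),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return bundle
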