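"""CSV exchange formats, study configuration and the end-to-end pipeline.

Two plain CSV schemas are used throughout (column names fixed, units
never inferred):

* study CSV: ``product_id, subject_id, time_hr, conc_mg_L,
  censored_flag, dose_mg`` — one row per plasma sample;
* dissolution CSV: ``product_id, time_min, pct_dissolved``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import bioeq, compartmental, dissolution, nca
from .datatypes import ConcentrationTimeProfile, DissolutionProfile

logger = logging.getLogger("pkdiss")

__all__ = [
    "StudyConfig",
    "read_study_csv",
    "write_study_csv",
    "read_dissolution_csv",
    "write_dissolution_csv",
    "run_pipeline",
    "validate_report",
]

STUDY_COLUMNS = [
    "product_id", "subject_id", "time_hr", "conc_mg_L", "censored_flag", "dose_mg",
]
DISSOLUTION_COLUMNS = ["product_id", "time_min", "pct_dissolved"]


@dataclass(frozen=True)
class StudyConfig:
    """Study-wide analysis settings."""

    dose: float = 500.0  # mg
    dosing_interval: float = 24.0  # hr
    loq: float = 0.05  # mg/L
    reference_brand: str = "F"
    alpha: float = 0.05
    seed: int = 0
    trapezoid_rule: str = "linear"  # or "linlog"
    f2_truncation: bool = False
    model_variant: str = "oral_first_order"

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.trapezoid_rule not in ("linear", "linlog"):
            raise ValueError("trapezoid_rule must be 'linear' or 'linlog'")
        if self.model_variant not in ("oral_first_order", "iv_biexponential"):
            raise ValueError("unknown model_variant")
        if self.dose <= 0 or self.dosing_interval <= 0 or self.loq < 0:
            raise ValueError("dose/dosing_interval must be > 0, loq >= 0")

    @classmethod
    def from_toml(cls, path: str | Path) -> "StudyConfig":
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


class ParseError(ValueError):
    pass


def read_study_csv(path: str | Path) -> list[ConcentrationTimeProfile]:
    """Load per-subject concentration profiles from a study CSV.

    Rows are grouped by (product_id, subject_id) and sorted by time;
    duplicated (subject, time) pairs are a parse error reported with
    their 1-based data line numbers.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in STUDY_COLUMNS if c not in df.columns and c != "product_id"]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    if "product_id" not in df.columns:
        df["product_id"] = ""
    df["product_id"] = df["product_id"].fillna("").astype(str)
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1
    dup = df.duplicated(subset=["product_id", "subject_id", "time_hr"], keep=False)
    if dup.any():
        lines = df.loc[dup, "_line"].tolist()
        raise ParseError(
            f"{path}: duplicated (subject, time) rows at lines {lines}"
        )
    profiles: list[ConcentrationTimeProfile] = []
    for (product, subject), g in df.groupby(["product_id", "subject_id"], sort=True):
        g = g.sort_values("time_hr")
        try:
            profiles.append(
                ConcentrationTimeProfile(
                    subject_id=str(subject),
                    times=g["time_hr"].to_numpy(dtype=float),
                    concentrations=g["conc_mg_L"].to_numpy(dtype=float),
                    dose=float(g["dose_mg"].iloc[0]),
                    censored=g["censored_flag"].to_numpy(dtype=bool),
                    product_id=str(product),
                )
            )
        except ValueError as exc:
            lines = g["_line"].tolist()
            raise ParseError(
                f"{path}: invalid profile for subject {subject!r} "
                f"(lines {lines}): {exc}"
            ) from exc
    return profiles


def write_study_csv(
    profiles: list[ConcentrationTimeProfile], path: str | Path
) -> None:
    rows = []
    for p in profiles:
        for t, c, cen in zip(p.times, p.concentrations, p.censored):
            rows.append(
                {
                    "product_id": p.product_id,
                    "subject_id": p.subject_id,
                    "time_hr": t,
                    "conc_mg_L": c,
                    "censored_flag": bool(cen),
                    "dose_mg": p.dose,
                }
            )
    pd.DataFrame(rows, columns=STUDY_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_dissolution_csv(path: str | Path) -> list[DissolutionProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DISSOLUTION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns {missing}")
    out = []
    for product, g in df.groupby("product_id", sort=True):
        g = g.sort_values("time_min")
        out.append(
            DissolutionProfile(
                product_id=str(product),
                times=g["time_min"].to_numpy(dtype=float),
                values=g["pct_dissolved"].to_numpy(dtype=float),
            )
        )
    return out


def write_dissolution_csv(
    profiles: list[DissolutionProfile], path: str | Path
) -> None:
    rows = []
    for p in profiles:
        for t, v in zip(p.times, p.values):
            rows.append(
                {"product_id": p.product_id, "time_min": t, "pct_dissolved": v}
            )
    pd.DataFrame(rows, columns=DISSOLUTION_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _group_by_brand(
    profiles: list[ConcentrationTimeProfile],
) -> dict[str, list[ConcentrationTimeProfile]]:
    out: dict[str, list[ConcentrationTimeProfile]] = {}
    for p in profiles:
        out.setdefault(p.product_id or "default", []).append(p)
    return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(
    config: StudyConfig,
    study_path: str | Path,
    dissolution_path: Optional[str | Path] = None,
    out_dir: Optional[str | Path] = None,
    fit_models: bool = True,
) -> dict:
    """Run dissolution comparison -> NCA -> compartmental fits -> brand
    statistics and return a JSON-serializable report.

    ``dissolution_path=None`` produces a PK-only report.  When
    ``out_dir`` is given, ``report.json`` and per-stage CSVs are
    written there.  Reports are deterministic for a fixed input and
    config (no timestamps).
    """
    report: dict = {"config": dataclasses.asdict(config), "stages": []}

    if dissolution_path is not None:
        diss = _stage("dissolution")(_dissolution_stage)(config, dissolution_path)
        report["dissolution"] = diss
        report["stages"].append("dissolution")

    profiles = _stage("read_study")(read_study_csv)(study_path)
    by_brand = _group_by_brand(profiles)

    nca_results = {
        brand: [
            nca.nca_full(
                p,
                dosing_interval=config.dosing_interval,
                method=config.trapezoid_rule,
            )
            for p in plist
        ]
        for brand, plist in by_brand.items()
    }
    report["nca"] = {
        brand: [r.to_dict() for r in results]
        for brand, results in nca_results.items()
    }
    report["stages"].append("nca")

    if fit_models:
        fits = _stage("compartmental")(_fit_stage)(config, by_brand)
        report["compartmental"] = fits
        report["stages"].append("compartmental")

    if len(by_brand) >= 2 and config.reference_brand in by_brand:
        stats_out = _stage("bioeq")(_bioeq_stage)(config, nca_results)
        report["bioeq"] = stats_out
        report["stages"].append("bioeq")

    validate_report(report)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        rows = [d for results in report["nca"].values() for d in results]
        pd.DataFrame(rows).to_csv(out / "nca.csv", index=False)
    return report


def _dissolution_stage(config: StudyConfig, path) -> dict:
    profiles = read_dissolution_csv(path)
    by_id = {p.product_id: p for p in profiles}
    if config.reference_brand not in by_id:
        raise ValueError(
            f"reference brand {config.reference_brand!r} not in dissolution file"
        )
    ref = by_id[config.reference_brand]
    tests = [p for p in profiles if p.product_id != config.reference_brand]
    table = dissolution.compare_all(tests, ref, config.f2_truncation)
    classes = {
        p.product_id: dissolution.classify_release(p).value for p in profiles
    }
    return {
        "comparison": table.to_dict(orient="records"),
        "release_class": classes,
    }


def _fit_stage(config: StudyConfig, by_brand) -> dict:
    out = {}
    for brand, plist in by_brand.items():
        rows = []
        for p in plist:
            try:
                fit = compartmental.fit_compartment_model(
                    p, variant=config.model_variant
                )
                rows.append(fit.to_dict())
            except ValueError as exc:
                logger.warning("fit failed for %s: %s", p.subject_id, exc)
        out[brand] = rows
    return out


def _bioeq_stage(config: StudyConfig, nca_results) -> dict:
    res = bioeq.run_bioeq_study(
        nca_results, config.reference_brand, alpha=config.alpha
    )
    return {
        "reference_brand": res.reference_brand,
        "fr_by_brand": res.fr_by_brand,
        "fr_mean_of_ratios": res.fr_mean_of_ratios,
        "interchangeable": res.interchangeable,
        "anova": {
            param: dataclasses.asdict(a) for param, a in res.anova_tables.items()
        },
        "tukey": {
            param: {
                f"{a}|{b}": dataclasses.asdict(pair)
                for (a, b), pair in pairs.items()
            }
            for param, pairs in res.tukey_flags.items()
        },
    }


_REPORT_REQUIRED = {"config": dict, "stages": list, "nca": dict}


def validate_report(report: dict) -> None:
    """Check the report's structural schema; raise ValueError if broken."""
    for key, typ in _REPORT_REQUIRED.items():
        if key not in report or not isinstance(report[key], typ):
            raise ValueError(f"report missing or mistyped key {key!r}")
    if "seed" not in report["config"]:
        raise ValueError("report config must record the seed")
    for brand, rows in report["nca"].items():
        for row in rows:
            if "auc_last" not in row or "cmax" not in row:
                raise ValueError(f"malformed NCA row for brand {brand!r}")
    if "bioeq" in report:
        for key in ("fr_by_brand", "anova", "tukey"):
            if key not in report["bioeq"]:
                raise ValueError(f"bioeq section missing {key!r}")
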