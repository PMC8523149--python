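"""Cohort-level orchestration: QC, all analysis stages, summary report.

Conventions enforced throughout: times in seconds with the injection at t=0,
half-open windows ``[start, end)``, 0-based frame indices.  A run is fully
determined by its configuration and inputs; every resampling operation draws
from a per-neuron substream of the run seed (stable CRC32 of the neuron's
qualified name), so results do not depend on processing order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .design import SessionDesign
from .movement import (
    compute_velocity,
    label_movement,
    sensitization_index,
    total_distance,
)
from .photometry import bin_dff, compute_dff, fit_control
from .responsiveness import (
    ResponseLabel,
    bonferroni,
    fisher_exact,
    fraction_responsive,
    label_neuron,
    log2_response,
    track_profiles,
)
from .transients import DetectorConfig, detect_transients

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "qc_filter", "run_all", "report_render", "validate_report"]


@dataclass
class RunConfig:
    """Everything a cohort run depends on; serialisable to YAML."""

    cohort_dir: str = "scratch/cohort"
    out_dir: str = "scratch/run"
    days: tuple[str, ...] = ("saline", "cocaine1", "cocaine8")
    seed: int = 0
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    n_shuffles: int = 10_000
    min_events: int = 5
    movement_n_shuffles: int = 10_000
    shift_range_s: tuple[float, float] = (10.0, 1200.0)
    qc_min_neurons: int = 20
    include_movement: bool = True
    include_photometry: bool = True
    #: photometry control-fit window: None = full recording, "pre" = before injection
    photometry_fit_window: str | None = "pre"
    photometry_bins: tuple[tuple[float, float], ...] = ((0.0, 300.0), (600.0, 900.0))
    #: animal -> cell-class tag; by default inferred from the animal-id prefix
    class_map: dict = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(json.loads(json.dumps(d))))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "detector" in d and isinstance(d["detector"], dict):
            det = d["detector"]
            if "tau_d_limits" in det:
                det["tau_d_limits"] = tuple(det["tau_d_limits"])
            d["detector"] = DetectorConfig(**det)
        for key in ("days", "shift_range_s"):
            if key in d:
                d[key] = tuple(d[key])
        if "photometry_bins" in d:
            d["photometry_bins"] = tuple(tuple(b) for b in d["photometry_bins"])
        return cls(**d)


def _neuron_seed(run_seed: int, qualified_name: str) -> int:
    """Stable, order-independent substream seed for one neuron."""
    return (int(run_seed) * 2_654_435_761 + zlib.crc32(qualified_name.encode())) % (2**31)


def _animal_class(animal: str, class_map: dict) -> str:
    if animal in class_map:
        return class_map[animal]
    return "D1-like" if animal.lower().startswith("d1") else "D2-like"


# ---------------------------------------------------------------------------
# QC


def discover_animals(cohort_dir: str | Path, days) -> list[str]:
    cohort = Path(cohort_dir)
    animals = set()
    for f in cohort.glob(f"*_{days[0]}_traces.csv"):
        animals.add(f.name[: -len(f"_{days[0]}_traces.csv")])
    return sorted(animals)


def qc_filter(
    cohort_dir: str | Path, days, min_neurons: int = 20
) -> tuple[list[str], list[dict]]:
    """Drop animals with fewer than ``min_neurons`` recorded neurons on any
    session (strict '<'); returns retained animals and the exclusion log."""
    kept, excluded = [], []
    for animal in discover_animals(cohort_dir, days):
        counts = {}
        for day in days:
            f = Path(cohort_dir) / f"{animal}_{day}_traces.csv"
            counts[day] = (
                int(pd.read_csv(f, usecols=["neuron_id"])["neuron_id"].nunique())
                if f.exists()
                else 0
            )
        n_min = min(counts.values())
        if n_min < min_neurons:
            excluded.append({"animal": animal, "neuron_counts": counts,
                             "reason": f"fewer_than_{min_neurons}_neurons"})
            logger.warning("QC: excluding %s (%s)", animal, counts)
        else:
            kept.append(animal)
    if not kept:
        raise RuntimeError("no animals left after QC")
    return kept, excluded


# ---------------------------------------------------------------------------
# stages


def _detect_stage(cfg: RunConfig, animals, designs) -> dict:
    """Transient detection for every animal/day; trains cached on disk."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trains: dict[tuple[str, str], dict] = {}
    for animal in animals:
        for day in cfg.days:
            design = designs[day]
            traces = sio.read_traces_csv(
                Path(cfg.cohort_dir) / f"{animal}_{day}_traces.csv", design
            )
            day_trains, all_events = [], {}
            for tr in traces:
                train, events, _ = detect_transients(tr, cfg.detector)
                day_trains.append(train)
                all_events[tr.neuron_id] = events
            sio.write_trains_json(day_trains, out / f"{animal}_{day}_trains.json")
            sio.events_to_frame(all_events, day).to_csv(
                out / f"{animal}_{day}_events.csv", index=False, float_format="%.5f"
            )
            trains[(animal, day)] = {t.neuron_id: t for t in day_trains}
    return trains


def _classify_stage(cfg: RunConfig, animals, designs, trains) -> dict:
    labels: dict[tuple[str, str], dict[str, ResponseLabel]] = {}
    out = Path(cfg.out_dir)
    for animal in animals:
        for day in cfg.days:
            design = designs[day]
            day_labels = {}
            for nid, train in trains[(animal, day)].items():
                seed = _neuron_seed(cfg.seed, f"resp/{animal}/{day}/{nid}")
                day_labels[nid] = label_neuron(
                    train, design, n_shuffles=cfg.n_shuffles,
                    seed=seed, min_events=cfg.min_events,
                )
            labels[(animal, day)] = day_labels
            sio.labels_to_frame(list(day_labels.values())).to_csv(
                out / f"{animal}_{day}_labels.csv", index=False
            )
    return labels


def _movement_stage(cfg: RunConfig, animals, designs, trains) -> dict:
    mlabels: dict[tuple[str, str], dict] = {}
    for animal in animals:
        for day in cfg.days:
            design = designs[day]
            track = sio.read_centroid_csv(
                Path(cfg.cohort_dir) / f"{animal}_{day}_centroid.csv"
            )
            vel = compute_velocity(track, design.frame_times())
            day_labels = {}
            for nid, train in trains[(animal, day)].items():
                seed = _neuron_seed(cfg.seed, f"mov/{animal}/{day}/{nid}")
                lab, _ = label_movement(
                    vel, train, design,
                    n_shuffles=cfg.movement_n_shuffles,
                    shift_range_s=cfg.shift_range_s, seed=seed,
                )
                day_labels[nid] = lab
            mlabels[(animal, day)] = day_labels
    return mlabels


def _photometry_stage(cfg: RunConfig, animals, designs) -> dict:
    out = {}
    for animal in animals:
        for day in cfg.days:
            f = Path(cfg.cohort_dir) / f"{animal}_{day}_photometry.csv"
            if not f.exists():
                continue
            sig = sio.read_photometry_csv(f)
            window = None
            if cfg.photometry_fit_window == "pre":
                window = (float(sig.times_s[0]), 0.0)
            coeffs = fit_control(sig, fit_window=window)
            dff = compute_dff(sig, coeffs)
            out[(animal, day)] = {
                "slope": coeffs.slope,
                "intercept": coeffs.intercept,
                "r_squared": coeffs.r_squared,
                "bins": {
                    f"{int(a)}-{int(b)}s": v
                    for (a, b), v in zip(
                        cfg.photometry_bins, bin_dff(dff, list(cfg.photometry_bins))
                    )
                },
            }
    return out


# ---------------------------------------------------------------------------
# summary


def _fraction_block(labels_list) -> dict:
    fr = fraction_responsive(labels_list)
    return {
        "n": fr["n"],
        "elevated": {"count": fr["counts"]["elevated"], "fraction": fr["fractions"]["elevated"]},
        "reduced": {"count": fr["counts"]["reduced"], "fraction": fr["fractions"]["reduced"]},
        "none": {"count": fr["counts"]["none"], "fraction": fr["fractions"]["none"]},
    }


def _fisher_family(day_blocks: dict, days, direction: str) -> list[dict]:
    """Pairwise day comparisons of responsive fractions, Bonferroni-adjusted
    within the family."""
    comps = []
    pairs = [(a, b) for i, a in enumerate(days) for b in days[i + 1 :]]
    raw_p = []
    for a, b in pairs:
        na, nb = day_blocks[a]["n"], day_blocks[b]["n"]
        ka, kb = day_blocks[a][direction]["count"], day_blocks[b][direction]["count"]
        table = [[ka, na - ka], [kb, nb - kb]]
        try:
            odds, p = fisher_exact(table)
        except ValueError:
            odds, p = float("nan"), 1.0
        raw_p.append(p)
        comps.append({"days": [a, b], "table": table, "odds_ratio": odds, "p_raw": p})
    adj = bonferroni(raw_p)
    for c, pa in zip(comps, adj):
        c["p_bonferroni"] = float(pa)
    return comps


def run_all(config: RunConfig) -> dict:
    """Execute every enabled stage and assemble the summary report."""
    cohort = Path(config.cohort_dir)
    designs = {
        day: SessionDesign.from_dict(
            json.loads((cohort / f"design_{day}.json").read_text())
        )
        for day in config.days
    }
    animals, excluded = qc_filter(cohort, config.days, config.qc_min_neurons)
    trains = _detect_stage(config, animals, designs)
    labels = _classify_stage(config, animals, designs, trains)

    classes = sorted({_animal_class(a, config.class_map) for a in animals})
    by_class_day: dict[str, dict[str, list[ResponseLabel]]] = {
        c: {d: [] for d in config.days} for c in classes
    }
    for (animal, day), day_labels in labels.items():
        c = _animal_class(animal, config.class_map)
        by_class_day[c][day].extend(day_labels.values())

    fractions = {
        c: {d: _fraction_block(v) for d, v in per_day.items() if v}
        for c, per_day in by_class_day.items()
    }
    comparisons = {
        c: {
            direction: _fisher_family(fractions[c], config.days, direction)
            for direction in ("elevated", "reduced")
        }
        for c in classes
        if len(fractions[c]) == len(config.days)
    }

    # cross-session profiles between the two cocaine days
    cross = {}
    d1, d8 = config.days[-2], config.days[-1]
    identity_path = cohort / "identity_map.json"
    if identity_path.exists():
        identity = sio.read_identity_map(identity_path)
        for c in classes:
            tallies_sum = {
                dr: {"both": 0, "last_exposure_only": 0, "first_exposure_only": 0, "never": 0}
                for dr in ("elevated", "reduced")
            }
            for animal in animals:
                if _animal_class(animal, config.class_map) != c:
                    continue
                amap = identity.get(animal, {}).get("tracked_ids", {})
                idmap = {tid: (m[d1], m[d8]) for tid, m in amap.items()}
                _, tallies = track_profiles(labels[(animal, d1)], labels[(animal, d8)], idmap)
                for dr in tallies_sum:
                    for k in tallies_sum[dr]:
                        tallies_sum[dr][k] += tallies[dr][k]
            cross[c] = tallies_sum

    # per-neuron response statistic used by the mixed-model analysis
    log2_stats = {
        c: {
            d: [log2_response(l.n_pre, l.n_post) for l in v]
            for d, v in per_day.items()
        }
        for c, per_day in by_class_day.items()
    }

    report: dict = {
        "config": json.loads(json.dumps(asdict(config))),
        "qc": {"animals": animals, "excluded": excluded},
        "fractions": fractions,
        "fisher_comparisons": comparisons,
        "cross_session": cross,
        "log2_response_mean": {
            c: {d: (float(np.mean(v)) if v else None) for d, v in per_day.items()}
            for c, per_day in log2_stats.items()
        },
    }

    if config.include_movement:
        mlabels = _movement_stage(config, animals, designs, trains)
        mv = {}
        for day in config.days:
            all_m = [m for a in animals for m in mlabels[(a, day)].values()]
            n = len(all_m)
            frac = {
                lab: sum(1 for m in all_m if m.label == lab) / n if n else None
                for lab in ("heightened", "lowered")
            }
            # movement coding within the cocaine-responsive subset
            resp_ids = {
                (a, nid)
                for a in animals
                for nid, l in labels[(a, day)].items()
                if l.label != "none"
            }
            sub = [
                m
                for a in animals
                for nid, m in mlabels[(a, day)].items()
                if (a, nid) in resp_ids
            ]
            frac_sub = {
                lab: (sum(1 for m in sub if m.label == lab) / len(sub)) if sub else None
                for lab in ("heightened", "lowered")
            }
            mv[day] = {
                "n": n,
                "fractions": frac,
                "n_cocaine_responsive": len(sub),
                "fractions_within_responsive": frac_sub,
            }
        report["movement"] = mv

    if config.include_photometry:
        ph = _photometry_stage(config, animals, designs)
        report["photometry"] = {f"{a}/{d}": v for (a, d), v in ph.items()}

    # locomotor sensitization between the two cocaine days
    sens = {}
    for animal in animals:
        try:
            t1 = sio.read_centroid_csv(cohort / f"{animal}_{d1}_centroid.csv")
            t8 = sio.read_centroid_csv(cohort / f"{animal}_{d8}_centroid.csv")
            sens[animal] = sensitization_index(total_distance(t1), total_distance(t8))
        except FileNotFoundError:
            continue
    report["sensitization_index"] = sens

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    (out / "report.txt").write_text(report_render(report))
    config.to_yaml(out / "config.yaml")
    return report


# ---------------------------------------------------------------------------
# rendering and validation


def report_render(report: dict) -> str:
    """Human-readable summary; every fraction printed with its counts."""
    lines = ["cohort summary", "=" * 60]
    for c, per_day in report.get("fractions", {}).items():
        lines.append(f"\n[{c}] fraction of responsive neurons")
        for day, blk in per_day.items():
            e, r = blk["elevated"], blk["reduced"]
            lines.append(
                f"  {day:>10}: elevated {e['count']:>3}/{blk['n']:<4}"
                f" ({e['fraction']:.3f})   reduced {r['count']:>3}/{blk['n']:<4}"
                f" ({r['fraction']:.3f})"
            )
    for c, fam in report.get("fisher_comparisons", {}).items():
        lines.append(f"\n[{c}] Fisher day comparisons (Bonferroni-adjusted)")
        for direction, comps in fam.items():
            for comp in comps:
                a, b = comp["days"]
                lines.append(
                    f"  {direction:>8} {a} vs {b}: OR={comp['odds_ratio']:.3g}"
                    f" p={comp['p_raw']:.3g} p_adj={comp['p_bonferroni']:.3g}"
                )
    for c, tallies in report.get("cross_session", {}).items():
        lines.append(f"\n[{c}] cross-session categories (day1 vs day8)")
        for direction, t in tallies.items():
            lines.append(f"  {direction}: {t}")
    if "movement" in report:
        lines.append("\nmovement-coding fractions")
        for day, blk in report["movement"].items():
            fr = blk["fractions"]

            def fmt(v):
                return "n/a" if v is None else f"{v:.3f}"

            lines.append(
                f"  {day:>10}: heightened {fmt(fr['heightened'])}"
                f" lowered {fmt(fr['lowered'])} (n={blk['n']};"
                f" within responsive n={blk['n_cocaine_responsive']})"
            )
    if report.get("sensitization_index"):
        lines.append("\nsensitization index (distance day8 / day1)")
        for a, v in report["sensitization_index"].items():
            lines.append(f"  {a}: {v:.3f}")
    if report.get("qc", {}).get("excluded"):
        lines.append("\nQC exclusions")
        for e in report["qc"]["excluded"]:
            lines.append(f"  {e['animal']}: {e['reason']} {e['neuron_counts']}")
    return "\n".join(lines) + "\n"


#: minimal structural schema for the machine-readable report
REPORT_SCHEMA = {
    "required": ["config", "qc", "fractions", "sensitization_index"],
    "fraction_keys": ["n", "elevated", "reduced", "none"],
}


def validate_report(report: dict) -> None:
    """Raise ValueError if the report lacks the required structure."""
    for key in REPORT_SCHEMA["required"]:
        if key not in report:
            raise ValueError(f"report missing section '{key}'")
    for c, per_day in report["fractions"].items():
        for day, blk in per_day.items():
            for k in REPORT_SCHEMA["fraction_keys"]:
                if k not in blk:
                    raise ValueError(f"fractions[{c}][{day}] missing '{k}'")
            total = sum(blk[k]["count"] for k in ("elevated", "reduced", "none"))
            if total != blk["n"]:
                raise ValueError("fraction counts do not sum to n")
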