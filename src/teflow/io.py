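"""Recording formats, study configuration, and the end-to-end study driver.

The canonical fixture format is a tab-separated channels x samples matrix
with a JSON sidecar carrying labels, rate and metadata — diff-able and
test-friendly.  A minimal BrainVision Core triple (.vhdr/.vmrk/.eeg,
IEEE float32 multiplexed) reader/writer is provided for realism, since
acquisition systems of the BrainVision family emit that layout.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from teflow import __version__ as _pkg_version
from teflow.flow import (
    TEMatrix,
    bootstrap_upper_threshold,
    common_channels,
    grand_average,
    neutral_contrast,
    pairwise_te,
    select_channels,
)
from teflow.montage import NEUTRAL_PAIRING
from teflow.preprocess import PreprocessConfig, preprocess_recording
from teflow.specificity import build_dataset, compare_weights, run_protocol, test_above_chance
from teflow.stats import kruskal_wallis_r, wilcoxon_r
from teflow.synthetic import CouplingSpec, Recording, SyntheticDesign, generate_recording
from teflow.te import TEConfig

logger = logging.getLogger(__name__)

__all__ = [
    "read_recording",
    "write_recording_tsv",
    "write_brainvision",
    "read_brainvision",
    "StudyConfig",
    "run_study",
]


# ---------------------------------------------------------------------------
# delimited matrix + JSON sidecar


def write_recording_tsv(rec: Recording, stem: str | Path) -> Path:
    """Write ``<stem>.tsv`` + ``<stem>.json``; returns the tsv path."""
    from teflow.synthetic import write_recording

    tsv, _ = write_recording(rec, stem)
    return tsv


def _read_tsv_pair(tsv: Path, delimiter: str = "\t") -> Recording:
    sidecar = tsv.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar for {tsv}: {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = np.loadtxt(tsv, delimiter=delimiter, ndmin=2)
    return Recording(
        data=data,
        labels=tuple(meta["labels"]),
        rate=float(meta["rate"]),
        subject_id=str(meta.get("subject", "S00")),
        condition=str(meta.get("condition", "baseline")),
    )


# ---------------------------------------------------------------------------
# minimal BrainVision Core triple


def write_brainvision(rec: Recording, stem: str | Path) -> Path:
    """Write ``<stem>.vhdr/.vmrk/.eeg`` (IEEE float32, multiplexed)."""
    stem = Path(stem)
    vhdr, vmrk, eeg = (stem.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    sampling_interval_us = 1e6 / rec.rate
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={rec.n_channels}",
        f"SamplingInterval={sampling_interval_us:.6f}",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(rec.labels, 1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    vmrk.write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={eeg.name}\n"
        "[Marker Infos]\n"
        f"Mk1=New Segment,,1,1,0\n",
        encoding="utf-8",
    )
    rec.data.T.astype("<f4").tofile(eeg)  # multiplexed: sample-major
    return vhdr


def read_brainvision(vhdr_path: str | Path) -> Recording:
    """Read a BrainVision Core triple written by :func:`write_brainvision`.

    Supports the BINARY / MULTIPLEXED / IEEE_FLOAT_32 layout (the one this
    package writes) and INT_16 with per-channel resolution.
    """
    vhdr_path = Path(vhdr_path)
    text = vhdr_path.read_text(encoding="utf-8", errors="replace")
    cp = configparser.ConfigParser(strict=False)
    try:
        # header starts with a non-INI banner line
        body = text.split("\n", 1)[1] if text.startswith("Brain Vision") else text
        cp.read_string(body)
        common = cp["Common Infos"]
        binary = cp["Binary Infos"]
        chans = cp["Channel Infos"]
    except (configparser.Error, KeyError) as exc:
        raise ValueError(f"malformed BrainVision header {vhdr_path}: {exc}") from exc
    if common.get("DataFormat", "BINARY").upper() != "BINARY":
        raise ValueError(f"{vhdr_path}: only BINARY DataFormat is supported")
    if common.get("DataOrientation", "MULTIPLEXED").upper() != "MULTIPLEXED":
        raise ValueError(f"{vhdr_path}: only MULTIPLEXED orientation is supported")
    n_ch = int(common["NumberOfChannels"])
    rate = 1e6 / float(common["SamplingInterval"])
    labels, resolutions = [], []
    for i in range(1, n_ch + 1):
        entry = chans[f"Ch{i}"]
        parts = entry.split(",")
        labels.append(parts[0])
        resolutions.append(float(parts[2]) if len(parts) > 2 and parts[2] else 1.0)
    fmt = binary.get("BinaryFormat", "IEEE_FLOAT_32").upper()
    eeg = vhdr_path.with_name(common["DataFile"])
    if fmt == "IEEE_FLOAT_32":
        raw = np.fromfile(eeg, dtype="<f4")
    elif fmt == "INT_16":
        raw = np.fromfile(eeg, dtype="<i2").astype(float)
    else:
        raise ValueError(f"{vhdr_path}: unsupported BinaryFormat {fmt}")
    if raw.size % n_ch:
        raise ValueError(f"{eeg}: size not a multiple of the channel count")
    data = raw.reshape(-1, n_ch).T * np.asarray(resolutions)[:, None]
    return Recording(data=data, labels=tuple(labels), rate=rate)


def read_recording(path: str | Path) -> Recording:
    """Load a recording from a ``.tsv``+sidecar pair or a ``.vhdr`` triple."""
    path = Path(path)
    if path.suffix == ".vhdr":
        return read_brainvision(path)
    if path.suffix in {".tsv", ".txt"}:
        return _read_tsv_pair(path)
    if path.suffix == "":
        return _read_tsv_pair(path.with_suffix(".tsv"))
    raise ValueError(f"unrecognized recording format: {path}")


# ---------------------------------------------------------------------------
# study configuration


@dataclass
class StudyConfig:
    """Everything a full study run needs, loadable from YAML.

    All randomness flows from ``seed`` through named substreams
    (synthesis / bootstrap / protocol), so one integer reproduces a run.
    """

    seed: int = 0
    design: SyntheticDesign | None = None
    conditions: tuple[str, ...] = ("NF", "NM", "AF", "AM", "EF", "EM")
    neutral_pairing: dict[str, str] = field(default_factory=lambda: dict(NEUTRAL_PAIRING))
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    te: TEConfig = field(default_factory=TEConfig)
    lag_range: tuple[int, int] = (0, 50)
    bootstrap_B: int = 10_000
    bootstrap_level: float = 95.0
    protocol_runs: int = 1000
    recordings_dir: Path | None = None

    def __post_init__(self) -> None:
        for setting, neutral in self.neutral_pairing.items():
            if neutral not in self.conditions:
                raise ValueError(
                    f"setting {setting} maps to unknown neutral {neutral}"
                )
        missing = [
            c for c in self.conditions
            if c not in self.neutral_pairing and c not in set(self.neutral_pairing.values())
        ]
        if missing:
            raise ValueError(
                f"conditions without a neutral pairing: {missing}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "StudyConfig":
        design = None
        if "design" in raw:
            d = dict(raw["design"])
            d["couplings"] = tuple(
                CouplingSpec(
                    source=c["source"], target=c["target"], delay=int(c["delay"]),
                    strength=float(c["strength"]),
                    conditions=frozenset(c.get("conditions", ["NF", "NM", "AF", "AM", "EF", "EM"])),
                )
                for c in d.get("couplings", [])
            )
            d.setdefault("seed", raw.get("seed", 0))
            design = SyntheticDesign(**d)
        pp = PreprocessConfig(**{k: tuple(v) if k == "band" else v
                                 for k, v in raw.get("preprocess", {}).items()})
        te_block = dict(raw.get("te", {}))
        lag_range = tuple(te_block.pop("lag_range", (0, 50)))
        te = TEConfig(**te_block)
        boot = raw.get("bootstrap", {})
        proto = raw.get("protocol", {})
        return cls(
            seed=int(raw.get("seed", 0)),
            design=design,
            conditions=tuple(raw.get("conditions", ("NF", "NM", "AF", "AM", "EF", "EM"))),
            neutral_pairing=dict(raw.get("neutral_pairing", NEUTRAL_PAIRING)),
            preprocess=pp,
            te=te,
            lag_range=lag_range,
            bootstrap_B=int(boot.get("B", 10_000)),
            bootstrap_level=float(boot.get("level", 95.0)),
            protocol_runs=int(proto.get("runs", 1000)),
            recordings_dir=Path(raw["recordings_dir"]) if raw.get("recordings_dir") else None,
        )


# ---------------------------------------------------------------------------
# end-to-end study


def _load_or_generate(cfg: StudyConfig, subject: str, condition: str) -> Recording:
    if cfg.recordings_dir is not None:
        stem = Path(cfg.recordings_dir) / f"{subject}_{condition}"
        return read_recording(stem.with_suffix(".tsv"))
    if cfg.design is None:
        raise ValueError("config provides neither recordings_dir nor a synthetic design")
    return generate_recording(cfg.design, subject, condition)


def run_study(cfg: StudyConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline and write every artifact plus a manifest.

    Stages: (synthesize or load) -> preprocess -> lag-optimized pairwise TE
    -> neutral contrast -> grand average -> bootstrap threshold -> channel
    selection -> common channels -> group statistics -> specificity
    protocol.  Any stage failure is re-raised with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _pkg_version,
        "seed": cfg.seed,
        "artifacts": {},
    }
    ss = np.random.SeedSequence(cfg.seed)
    boot_rng, proto_seed_seq = (np.random.default_rng(s) for s in ss.spawn(2))
    proto_seed = int(proto_seed_seq.integers(2**31))

    n_subjects = cfg.design.n_subjects if cfg.design is not None else 1
    subjects = [f"S{i:02d}" for i in range(n_subjects)]

    def _record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {
            "path": str(path.relative_to(outdir)),
            "sha256": hashlib.sha256(path.read_bytes()).hexdigest(),
        }

    # --- per subject x condition TE matrices
    te_mats: dict[tuple[str, str], TEMatrix] = {}
    for cond in cfg.conditions:
        for subj in subjects:
            stage = f"te[{subj},{cond}]"
            try:
                rec = _load_or_generate(cfg, subj, cond)
                clean, _ = preprocess_recording(rec, cfg.preprocess)
                te_mats[(subj, cond)] = pairwise_te(clean, cfg.te, cfg.lag_range)
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
    for (subj, cond), mat in te_mats.items():
        p = outdir / f"te_{subj}_{cond}.csv"
        mat.to_frame().to_csv(p)
        _record(f"te/{subj}/{cond}", p)
        pl = outdir / f"lags_{subj}_{cond}.csv"
        pd.DataFrame(mat.lags, index=list(mat.labels), columns=list(mat.labels)).to_csv(pl)
        _record(f"lags/{subj}/{cond}", pl)

    # --- contrast, average, threshold, select
    settings = sorted(cfg.neutral_pairing)
    selections: dict[str, frozenset[str]] = {}
    flows = {}
    grand: dict[str, TEMatrix] = {}
    for setting in settings:
        neutral = cfg.neutral_pairing[setting]
        contrasts = [
            neutral_contrast(te_mats[(s, setting)], te_mats[(s, neutral)])
            for s in subjects
        ]
        avg = grand_average(contrasts)
        grand[setting] = avg
        flow = bootstrap_upper_threshold(avg, B=cfg.bootstrap_B,
                                         level=cfg.bootstrap_level, seed=boot_rng)
        selections[setting] = select_channels(flow, B=cfg.bootstrap_B,
                                              level=cfg.bootstrap_level, seed=boot_rng)
        flows[setting] = flow
        p = outdir / f"flow_{setting}.csv"
        pd.DataFrame(flow.surviving, index=list(flow.labels), columns=list(flow.labels)).to_csv(p)
        _record(f"flow/{setting}", p)
    if len(selections) >= 2:
        common, dropped = common_channels(selections)
    else:  # single-setting study: its own selection stands in for the intersection
        only = next(iter(selections.values()))
        common = frozenset(only)
        dropped = tuple(s for s, v in selections.items() if not v)
    summary = {
        "selected_channels": {s: sorted(v) for s, v in selections.items()},
        "thresholds": {s: flows[s].threshold for s in settings},
        "common_channels": sorted(common),
        "dropped_settings": list(dropped),
    }

    # --- group statistics + specificity on the retained settings
    retained = [s for s in settings if s not in dropped]
    stats_out: dict = {}
    if common and len(retained) >= 2:
        pooled = {
            s: np.concatenate([
                flows[s].surviving[list(flows[s].labels).index(ch)] for ch in sorted(common)
            ])
            for s in retained
        }
        kw = kruskal_wallis_r([pooled[s] for s in retained])
        stats_out["kruskal_wallis"] = {
            "H": kw.statistic, "df": kw.df, "p": kw.p, "r": kw.effect_r,
            "magnitude": kw.magnitude,
        }
        stats_out["pairwise"] = {}
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                res = wilcoxon_r(pooled[a], pooled[b], mode="ranksum")
                stats_out["pairwise"][f"{a}_vs_{b}"] = {
                    "W": res.statistic, "df": res.df, "p": res.p, "r": res.effect_r,
                }
        per_setting = {
            s: {ch: flows[s].surviving[list(flows[s].labels).index(ch)] for ch in sorted(common)}
            for s in retained
        }
        try:
            ds = build_dataset(per_setting)
            report = run_protocol(ds, runs=cfg.protocol_runs, seed=proto_seed)
            above = test_above_chance(report)
            omnibus, pairwise_w = compare_weights(report)
            spec_out = report.to_dict()
            spec_out["above_chance"] = {
                "W": above.statistic, "p": above.p, "r": above.effect_r,
            }
            spec_out["weights_kruskal_wallis"] = {
                "H": omnibus.statistic, "p": omnibus.p, "r": omnibus.effect_r,
            }
            spec_out["weights_pairwise"] = {
                f"{a}_vs_{b}": {"W": res.statistic, "p": res.p, "r": res.effect_r}
                for (a, b), res in pairwise_w.items()
            }
            sp = outdir / "specificity.json"
            sp.write_text(json.dumps(spec_out, indent=1))
            _record("specificity", sp)
        except ValueError as exc:
            logger.warning("specificity protocol skipped: %s", exc)
            stats_out["specificity_skipped"] = str(exc)

    summary["group_stats"] = stats_out
    sj = outdir / "summary.json"
    sj.write_text(json.dumps(summary, indent=1, default=str))
    _record("summary", sj)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return outdir
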