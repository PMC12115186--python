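"""Pipeline orchestration: configuration, staging and reporting.

Stages run in dependency order — density/structure first, transport (which
needs the structural thickness δ), and the DSC stage independently. A stage
failure is recorded in the report and its dependents are skipped rather
than aborting the run. Reports are plain JSON with a provenance block
(config echo, package version, input checksums); no timestamps, so the same
config and seed give byte-identical reports.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .dsc import delta_report, hysteresis, transition_params
from .io import read_probe_csv, read_thermogram_csv, read_trajectory
from .structure import StructureConfig, structure_summary
from .transport import TransportConfig, transport_summary

log = logging.getLogger("membkit.pipeline")

EXIT_OK, EXIT_CONFIG, EXIT_FORMAT, EXIT_STAGE = 0, 2, 3, 4


@dataclass
class PipelineConfig:
    stages: list[str] = field(default_factory=lambda: ["structure"])
    trajectory: str | None = None
    roles: str | None = None
    probe_trajectory: str | None = None
    dsc_control: tuple[str, str] | None = None   # (heating, cooling) CSVs
    dsc_treated: tuple[str, str] | None = None
    dsc_ratio_label: str = ""
    discard_fraction: float = 0.2
    bin_width: float = 0.5
    hbond_cutoff: float = 3.5
    hbond_angle_deg: float = 30.0
    fit_window_ns: tuple[float, float] | None = None
    d_m_estimator: str = "dz"
    output_dir: str = "."
    seed: int = 20240563
    log_level: str = "INFO"

    def validate(self) -> None:
        known = {"structure", "transport", "dsc"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if not 0.0 <= self.discard_fraction <= 0.9:
            raise ValueError("discard_fraction must be in [0, 0.9]")
        if "structure" in self.stages and not self.trajectory:
            raise ValueError("structure stage needs a trajectory path")
        if "transport" in self.stages and not (self.probe_trajectory or self.trajectory):
            raise ValueError("transport stage needs a probe or bilayer trajectory")
        if "dsc" in self.stages and not (self.dsc_control and self.dsc_treated):
            raise ValueError("dsc stage needs control and treated thermogram pairs")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dsc_control", "dsc_treated", "fit_window_ns"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and write ``report.json``.

    Returns the report dict; per-stage status is "ok", "failed: <msg>" or
    "skipped: <reason>".
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    inputs = {}
    for p in [config.trajectory, config.roles, config.probe_trajectory,
              *(config.dsc_control or ()), *(config.dsc_treated or ())]:
        if p:
            inputs[p] = _checksum(p)

    report: dict = {
        "provenance": {
            "package": "membkit", "version": __version__,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(config).items()},
            "input_checksums": inputs,
        },
        "stages": {},
    }

    struct = None
    if "structure" in config.stages:
        try:
            traj = read_trajectory(config.trajectory, roles=config.roles)
            struct = structure_summary(traj, StructureConfig(
                discard_fraction=config.discard_fraction,
                bin_width=config.bin_width))
            report["stages"]["structure"] = {"status": "ok",
                                             "summary": struct.to_dict()}
        except Exception as exc:  # stage isolation is the contract
            log.error("structure stage failed: %s", exc)
            report["stages"]["structure"] = {"status": f"failed: {exc}"}

    if "transport" in config.stages:
        st = report["stages"].get("structure", {})
        if "structure" in config.stages and st.get("status") != "ok":
            report["stages"]["transport"] = {
                "status": "skipped: structure stage failed (no thickness)"}
        else:
            try:
                ptraj = read_probe_csv(config.probe_trajectory)
                delta = struct.thickness.mean if struct else _require_thickness(config)
                window = None
                if config.fit_window_ns is not None:
                    window = (config.fit_window_ns[0] * 1000.0,
                              config.fit_window_ns[1] * 1000.0)
                tsum = transport_summary(ptraj, delta, TransportConfig(
                    discard_fraction=config.discard_fraction,
                    fit_window=window, d_m_estimator=config.d_m_estimator))
                report["stages"]["transport"] = {"status": "ok",
                                                 "summary": tsum.to_dict()}
            except Exception as exc:
                log.error("transport stage failed: %s", exc)
                report["stages"]["transport"] = {"status": f"failed: {exc}"}

    if "dsc" in config.stages:
        try:
            ch = transition_params(read_thermogram_csv(config.dsc_control[0]))
            cc = transition_params(read_thermogram_csv(config.dsc_control[1]))
            th = transition_params(read_thermogram_csv(config.dsc_treated[0]))
            tc = transition_params(read_thermogram_csv(config.dsc_treated[1]))
            rep = delta_report((th, tc), (ch, cc), config.dsc_ratio_label)
            report["stages"]["dsc"] = {"status": "ok", "summary": {
                "control": {"t_m": ch.t_m, "delta_t_b": ch.delta_t_b,
                            "delta_h": ch.delta_h,
                            "delta_t_h": hysteresis(ch, cc)},
                "treated": {"t_m": th.t_m, "delta_t_b": th.delta_t_b,
                            "delta_h": th.delta_h,
                            "delta_t_h": hysteresis(th, tc)},
                "delta": asdict(rep),
            }}
        except Exception as exc:
            log.error("dsc stage failed: %s", exc)
            report["stages"]["dsc"] = {"status": f"failed: {exc}"}

    out = outdir / "report.json"
    out.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    log.info("report written to %s", out)
    return report


def _require_thickness(config: PipelineConfig) -> float:
    raise ValueError("transport stage without a structure stage needs an "
                     "explicit membrane thickness")
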