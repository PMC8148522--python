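"""On-disk formats: stats bundles, PMF/committor/I-V tables, run manifests.

A *stats bundle* is a single JSON document holding everything a downstream
reconstruction needs: the free-energy surface and grid, the applied
voltage, the detailed-balance weight, and the paired forward/backward
ensemble statistics of every replicate set (per-bin arrays stored as JSON
lists).  Bundles written with the same seeds are bit-for-bit identical.

Tabular outputs (PMF profiles, committors, I-V rows) are tab-separated
text with a single ``#``-prefixed header line, readable by any plotting
tool.
"""

from __future__ import annotations

import json
import time
import uuid
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .estimators import CommittorProfile
from .profiles import AppliedVoltage, FreeEnergySurface
from .reconstruct import PMFEstimate
from .simulator import EnsembleStats

__all__ = [
    "StatsBundle",
    "save_bundle",
    "load_bundle",
    "write_pmf_tsv",
    "write_committor_tsv",
    "RunManifest",
]

_ARRAY_FIELDS = ("bin_centers", "N_reach", "n_cross_per_bin")


def _stats_to_dict(s: EnsembleStats) -> dict:
    return {
        "direction": s.direction,
        "n_injected": int(s.n_injected),
        "n_cross": int(s.n_cross),
        "n_return": int(s.n_return),
        "n_truncated": int(s.n_truncated),
        "bin_centers": [float(x) for x in s.bin_centers],
        "N_reach": [int(x) for x in s.N_reach],
        "rho": [float(x) for x in s.rho],
        "seed": int(s.seed),
        "delta_v": float(s.delta_v),
        "dt": float(s.dt),
        "epsilon": float(s.epsilon),
        "bin_width": float(s.bin_width),
    }


def _stats_from_dict(d: dict) -> EnsembleStats:
    return EnsembleStats(
        direction=d["direction"],
        n_injected=d["n_injected"],
        n_cross=d["n_cross"],
        n_return=d["n_return"],
        n_truncated=d["n_truncated"],
        bin_centers=np.asarray(d["bin_centers"], dtype=float),
        N_reach=np.asarray(d["N_reach"], dtype=np.int64),
        rho=np.asarray(d["rho"], dtype=float),
        seed=d["seed"],
        delta_v=d["delta_v"],
        dt=d["dt"],
        epsilon=d["epsilon"],
        bin_width=d["bin_width"],
    )


@dataclass(frozen=True)
class StatsBundle:
    """All simulation statistics needed for reconstruction, one ion."""

    surface: FreeEnergySurface
    voltage: AppliedVoltage
    sets: list  # list of (forward EnsembleStats, backward EnsembleStats)
    w: float | None = None          # detailed-balance weight, if calibrated
    root_seed: int | None = None
    manifest_id: str | None = None


def save_bundle(bundle: StatsBundle, path: str | Path) -> None:
    doc = {
        "format": "edchannel-stats-bundle",
        "version": 1,
        "package_version": __version__,
        "manifest_id": bundle.manifest_id,
        "root_seed": bundle.root_seed,
        "w": bundle.w,
        "surface": {
            "z": [float(x) for x in bundle.surface.z],
            "A": [float(x) for x in bundle.surface.A],
            "D": float(bundle.surface.D),
            "q": float(bundle.surface.q),
            "T": float(bundle.surface.T),
            "ion_label": bundle.surface.ion_label,
        },
        "voltage": {
            "delta_v": float(bundle.voltage.delta_v),
            "z_a": float(bundle.voltage.z_a),
            "z_b": float(bundle.voltage.z_b),
        },
        "sets": [
            {"forward": _stats_to_dict(f), "backward": _stats_to_dict(b)}
            for f, b in bundle.sets
        ],
    }
    Path(path).write_text(json.dumps(doc))


def load_bundle(path: str | Path) -> StatsBundle:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "edchannel-stats-bundle":
        raise ValueError(f"{path} is not a stats bundle")
    s = doc["surface"]
    surface = FreeEnergySurface(
        z=np.asarray(s["z"], dtype=float),
        A=np.asarray(s["A"], dtype=float),
        D=s["D"], q=s["q"], T=s["T"], ion_label=s["ion_label"],
    )
    v = doc["voltage"]
    voltage = AppliedVoltage(delta_v=v["delta_v"], z_a=v["z_a"], z_b=v["z_b"])
    sets = [
        (_stats_from_dict(e["forward"]), _stats_from_dict(e["backward"]))
        for e in doc["sets"]
    ]
    return StatsBundle(surface=surface, voltage=voltage, sets=sets,
                       w=doc.get("w"), root_seed=doc.get("root_seed"),
                       manifest_id=doc.get("manifest_id"))


def write_pmf_tsv(estimate: PMFEstimate, path: str | Path) -> None:
    """Plot-ready PMF table: z, ΔA (kcal/mol), valid flag."""
    with open(path, "w") as fh:
        fh.write(f"# z_A\tdelta_A_kcal_mol\tvalid\tmethod={estimate.method}"
                 f"\tdelta_v_mV={estimate.delta_v:g}\n")
        for i in range(estimate.z.size):
            da = estimate.delta_A[i]
            fh.write(f"{estimate.z[i]:.6g}\t"
                     f"{'nan' if np.isnan(da) else f'{da:.6g}'}\t"
                     f"{int(estimate.valid[i])}\n")


def write_committor_tsv(profile: CommittorProfile, path: str | Path) -> None:
    """Plot-ready committor table: z, P, binomial SE, valid flag."""
    with open(path, "w") as fh:
        fh.write(f"# z_A\tP\tse\tvalid\tmethod={profile.method}\n")
        for i in range(profile.z.size):
            p = profile.P[i]
            fh.write(f"{profile.z[i]:.6g}\t"
                     f"{'nan' if np.isnan(p) else f'{p:.6g}'}\t"
                     f"{profile.se[i]:.6g}\t{int(profile.valid[i])}\n")


@dataclass
class RunManifest:
    """Provenance record tying one CLI run's outputs together."""

    config: dict
    seeds: dict
    manifest_id: str = field(default_factory=lambda: uuid.uuid4().hex[:12])
    package_version: str = __version__
    outputs: dict = field(default_factory=dict)
    wall_clock_s: dict = field(default_factory=dict)

    def record_stage(self, name: str, path: str | Path,
                     started_at: float) -> None:
        self.outputs[name] = str(path)
        self.wall_clock_s[name] = round(time.monotonic() - started_at, 3)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @staticmethod
    def load(path: str | Path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))
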