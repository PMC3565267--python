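"""Extended-XYZ trajectory I/O and declarative run configuration.

The dialect carries chain identity per sphere: the comment line holds
``Lattice="Lx 0 0 0 Ly 0 0 0 Lz"``, ``sigma=<value>`` and ``phi=<value>``;
per-atom columns are the element tag ``HS``, x, y, z, chain_id (0-based)
and index_in_chain.  One frame per configuration; a trajectory is a
concatenation of frames.  Coordinates are rescaled by the recorded sigma on
read, so files written in other length units load correctly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import numpy as np
import yaml

from .core import (
    ChainSystem,
    ConfigurationError,
    EnsembleSpec,
    SimulationBox,
    packing_fraction,
    validate,
)

#: schema version embedded in CSV output headers
CSV_SCHEMA = "chainpack-csv-1"


class FormatError(ConfigurationError):
    """Malformed trajectory file."""


def _comment_line(system: ChainSystem) -> str:
    L = system.box.edge_lengths
    lattice = f"{L[0]:.17g} 0 0 0 {L[1]:.17g} 0 0 0 {L[2]:.17g}"
    return (
        f'Lattice="{lattice}" '
        'Properties=species:S:1:pos:R:3:chain_id:I:1:index_in_chain:I:1 '
        f"sigma=1.0 phi={packing_fraction(system):.10g}"
    )


def write_frames(path: str | Path | TextIO, frames: Iterable[ChainSystem]) -> None:
    """Write one or more configurations in the extended-XYZ dialect."""
    close = False
    if not hasattr(path, "write"):
        fh: TextIO = open(path, "w")
        close = True
    else:
        fh = path
    try:
        for system in frames:
            cid, idx = system.chain_ids()
            fh.write(f"{system.n_at}\n")
            fh.write(_comment_line(system) + "\n")
            for i, p in enumerate(system.positions):
                fh.write(
                    f"HS {p[0]:.17g} {p[1]:.17g} {p[2]:.17g} {cid[i]} {idx[i]}\n"
                )
    finally:
        if close:
            fh.close()


def _parse_comment(line: str, lineno: int) -> tuple[np.ndarray, float]:
    import re

    m = re.search(r'Lattice="([^"]+)"', line)
    if not m:
        raise FormatError(f"line {lineno}: missing Lattice=... in frame header")
    vals = [float(x) for x in m.group(1).split()]
    if len(vals) != 9:
        raise FormatError(f"line {lineno}: Lattice needs 9 numbers")
    M = np.array(vals).reshape(3, 3)
    if np.any(np.abs(M - np.diag(np.diag(M))) > 1e-12):
        raise FormatError(f"line {lineno}: only orthorhombic lattices supported")
    sm = re.search(r"sigma=([0-9.eE+-]+)", line)
    sigma = float(sm.group(1)) if sm else 1.0
    if sigma <= 0:
        raise FormatError(f"line {lineno}: sigma must be positive")
    return np.diag(M), sigma


def read_frames(
    path: str | Path | TextIO, permissive: bool = False
) -> Iterator[ChainSystem | tuple[ChainSystem, "ValidityReport"]]:  # noqa: F821
    """Iterate over frames of an extended-XYZ trajectory.

    Every yielded frame passes :func:`validate`; under ``permissive=True``
    invalid frames are yielded as ``(system, report)`` tuples instead of
    raising.  Coordinates and the box are rescaled to sigma = 1 on read.
    """
    if hasattr(path, "read"):
        fh: TextIO = path
        close = False
    else:
        fh = open(path)
        close = True
    try:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            header = header.strip()
            if not header:
                continue
            try:
                n_at = int(header)
            except ValueError as e:
                raise FormatError(f"line {lineno}: expected atom count") from e
            comment = fh.readline()
            lineno += 1
            edges, sigma = _parse_comment(comment, lineno)
            pos = np.empty((n_at, 3))
            cid = np.empty(n_at, dtype=np.int64)
            idx = np.empty(n_at, dtype=np.int64)
            for i in range(n_at):
                line = fh.readline()
                lineno += 1
                parts = line.split()
                if len(parts) < 6:
                    raise FormatError(
                        f"line {lineno}: need 'HS x y z chain_id index_in_chain'"
                    )
                pos[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
                cid[i] = int(parts[4])
                idx[i] = int(parts[5])
            chains = _chains_from_columns(cid, idx, lineno)
            box = SimulationBox(edges / sigma)
            system = ChainSystem(pos / sigma, chains, box)
            report = validate(system)
            if report.ok:
                yield (system, report) if permissive else system
            elif permissive:
                yield system, report
            else:
                raise FormatError(
                    f"frame ending at line {lineno} is invalid: {report}"
                )
    finally:
        if close:
            fh.close()


def _chains_from_columns(
    cid: np.ndarray, idx: np.ndarray, lineno: int
) -> list[np.ndarray]:
    chains: list[np.ndarray] = []
    for c in np.unique(cid):
        sites = np.nonzero(cid == c)[0]
        order = idx[sites]
        if sorted(order) != list(range(sites.size)):
            raise FormatError(
                f"frame ending at line {lineno}: chain {c} has duplicate or "
                f"missing index_in_chain values"
            )
        chains.append(sites[np.argsort(order)])
    return chains


def csv_header(kind: str) -> str:
    """Schema comment line embedded at the top of every CSV output."""
    return f"# schema={CSV_SCHEMA} table={kind}\n"


# ---------------------------------------------------------------------------
# declarative run configuration


_KNOWN_KEYS = {
    "seed",
    "n_steps",
    "record_every",
    "phi_target",
    "movemix",
    "ensemble",
    "cb_schedule",
    "libration_delta_deg",
    "flipper_amplitudes",
    "gr_bin_width",
    "cce_threshold",
    "output",
}


@dataclass
class RunConfig:
    """Single declarative document for a full generate/compress/run/analyze
    pipeline; round-trips losslessly through YAML and rejects unknown keys."""

    seed: int = 0
    n_steps: int = 1_000_000
    record_every: int = 200_000
    phi_target: float | None = None
    movemix: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=lambda: {"distribution": "uniform", "n_av": 12, "delta": 0.5})
    cb_schedule: dict = field(default_factory=dict)
    libration_delta_deg: float = 20.0
    flipper_amplitudes: tuple[float, ...] = (0.01, 0.10, 1.00)
    gr_bin_width: float = 0.02
    cce_threshold: float = 0.245
    output: str = "."

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.flipper_amplitudes, list):
            cfg.flipper_amplitudes = tuple(cfg.flipper_amplitudes)
        return cfg

    def to_yaml(self) -> str:
        d = asdict(self)
        d["flipper_amplitudes"] = list(d["flipper_amplitudes"])
        return yaml.safe_dump(d, sort_keys=True)

    def build_ensemble(self) -> EnsembleSpec:
        return EnsembleSpec(**self.ensemble)

    def build_runspec(self):
        from .mc import CBSchedule, MoveMix, RunSpec

        import math as _math

        return RunSpec(
            n_steps=int(self.n_steps),
            seed=int(self.seed),
            record_every=int(self.record_every),
            movemix=MoveMix(**self.movemix) if self.movemix else MoveMix(),
            ensemble=self.build_ensemble(),
            cb_schedule=CBSchedule(**{
                k: tuple(v) for k, v in self.cb_schedule.items()
            }) if self.cb_schedule else CBSchedule(),
            libration_delta=_math.radians(self.libration_delta_deg),
        )

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
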