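"""File formats, configuration and synthetic fixture generation.

Everything is plain delimited text with ``#``-prefixed metadata headers,
mirroring the exports of AFM / optical-tweezers instruments: rupture
forces are one pN value per line; force--distance curves are two columns
(distance um, force pN); (velocity, peak force) tables are two columns
(um/s, pN).  Configuration is a single YAML file whose sections map onto
the library's objects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .estimators import (
    ConstantRateFamily,
    PowerLawFamily,
    ProtocolFamily,
    VelocityPeakPair,
    WLCFamily,
    predict_peak_forces,
)
from .kinetics import BondParameters, RuptureModel
from .montecarlo import RuptureDataset
from .protocols import (
    DEFAULT_KBT,
    ConstantRateProtocol,
    LoadingProtocol,
    PowerLawProtocol,
    WLCProtocol,
    tabulated_from_samples,
)

__all__ = [
    "RunConfig",
    "read_rupture_forces",
    "write_rupture_forces",
    "read_force_distance",
    "write_force_distance",
    "read_velocity_peaks",
    "write_velocity_peaks",
    "protocol_from_config",
    "family_from_config",
    "generate_fixtures",
]

_META_PREFIX = "# meta "


def _write_header(fh, meta: dict) -> None:
    for key, value in meta.items():
        fh.write(f"{_META_PREFIX}{key} = {json.dumps(value)}\n")


def _parse_header(lines) -> dict:
    meta = {}
    for line in lines:
        if not line.startswith(_META_PREFIX):
            continue
        key, _, raw = line[len(_META_PREFIX):].partition("=")
        try:
            meta[key.strip()] = json.loads(raw.strip())
        except json.JSONDecodeError:
            meta[key.strip()] = raw.strip()
    return meta


def _read_columns(path, n_cols: int) -> tuple[np.ndarray, dict]:
    path = Path(path)
    rows, header = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                header.append(stripped)
                continue
            parts = stripped.replace(",", " ").split()
            try:
                values = [float(p) for p in parts]
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric data on line {lineno}: {stripped!r}"
                ) from None
            if len(values) != n_cols:
                raise ValueError(
                    f"{path}: expected {n_cols} column(s) on line {lineno}, "
                    f"got {len(values)}"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float), _parse_header(header)


def read_rupture_forces(path) -> RuptureDataset:
    """Read a single-column rupture-force file (pN, '#' comments allowed).

    Metadata written by :func:`write_rupture_forces` (seed, velocity,
    protocol) is recovered from the header.
    """
    data, meta = _read_columns(path, 1)
    return RuptureDataset(
        forces=data[:, 0],
        velocity=meta.get("velocity_um_per_s"),
        protocol=meta.get("protocol"),
        seed=meta.get("seed"),
        meta=meta,
    )


def write_rupture_forces(path, dataset: RuptureDataset, extra_meta: dict | None = None) -> None:
    """Write rupture forces as single-column text with a metadata header."""
    meta = {
        "format": "rupture_forces",
        "units": "pN",
        "n": dataset.n,
    }
    if dataset.velocity is not None:
        meta["velocity_um_per_s"] = dataset.velocity
    if dataset.protocol is not None:
        meta["protocol"] = dataset.protocol
    if dataset.seed is not None:
        meta["seed"] = dataset.seed
    if dataset.params is not None:
        meta["bond"] = {"xb_nm": dataset.params.xb,
                        "koff_th_per_s": dataset.params.koff_th,
                        "kbt_pN_nm": dataset.params.kbt}
    if extra_meta:
        meta.update(extra_meta)
    with open(path, "w") as fh:
        _write_header(fh, meta)
        for f in dataset.forces:
            fh.write(f"{f:.10g}\n")


def read_force_distance(path) -> tuple[np.ndarray, dict]:
    """Read a two-column force--distance curve (L um, F pN)."""
    return _read_columns(path, 2)


def write_force_distance(path, L: np.ndarray, F: np.ndarray,
                         meta: dict | None = None) -> None:
    header = {"format": "force_distance", "units": "um pN"}
    if meta:
        header.update(meta)
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("# distance_um force_pN\n")
        for l_val, f_val in zip(L, F):
            fh.write(f"{l_val:.10g} {f_val:.10g}\n")


def read_velocity_peaks(path) -> list[VelocityPeakPair]:
    """Read a two-column (velocity um/s, peak force pN) table."""
    data, _ = _read_columns(path, 2)
    return [VelocityPeakPair(v=row[0], f_star=row[1]) for row in data]


def write_velocity_peaks(path, pairs, meta: dict | None = None) -> None:
    header = {"format": "velocity_peaks", "units": "um/s pN"}
    if meta:
        header.update(meta)
    with open(path, "w") as fh:
        _write_header(fh, header)
        fh.write("# velocity_um_per_s peak_force_pN\n")
        for p in pairs:
            fh.write(f"{p.v:.10g} {p.f_star:.10g}\n")


def protocol_from_config(cfg: dict) -> LoadingProtocol:
    """Build a loading protocol from a config mapping.

    Keys: ``type`` in {linear, power_law, wlc, tabulated} plus the
    type's parameters (``rate`` or ``a1``/``a2``-style coefficients with
    ``v``; ``lp``/``lc``/``v``/``kbt``; ``path``/``v``/``smooth_window``).
    """
    cfg = dict(cfg)
    kind = cfg.pop("type")
    if kind == "linear":
        if "rate" in cfg:
            return ConstantRateProtocol(rate=float(cfg["rate"]),
                                        v=cfg.get("v"))
        return PowerLawProtocol(coefficient=float(cfg["a1"]), exponent=1,
                                v=float(cfg["v"]))
    if kind == "power_law":
        if "coefficient" in cfg:
            coeff, n = float(cfg["coefficient"]), int(cfg["exponent"])
        else:
            ns = [k for k in cfg if k.startswith("a") and k[1:].isdigit()]
            if len(ns) != 1:
                raise ValueError("power_law config needs a single a<n> key")
            n = int(ns[0][1:])
            coeff = float(cfg[ns[0]])
        return PowerLawProtocol(coefficient=coeff, exponent=n,
                                v=float(cfg["v"]))
    if kind == "wlc":
        return WLCProtocol(lp=float(cfg["lp"]), Lc=float(cfg["lc"]),
                           v=float(cfg["v"]),
                           kbt=float(cfg.get("kbt", DEFAULT_KBT)))
    if kind == "tabulated":
        data, _ = read_force_distance(cfg["path"])
        return tabulated_from_samples(data, v=float(cfg["v"]),
                                      smooth_window=int(cfg.get("smooth_window", 0)))
    raise ValueError(f"unknown protocol type {kind!r}")


def family_from_config(cfg: dict) -> ProtocolFamily:
    """Velocity-indexed protocol family from a config mapping."""
    cfg = dict(cfg)
    kind = cfg.pop("type")
    if kind == "wlc":
        return WLCFamily(lp=float(cfg["lp"]), Lc=float(cfg["lc"]),
                         kbt=float(cfg.get("kbt", DEFAULT_KBT)))
    if kind == "power_law":
        return PowerLawFamily(coefficient=float(cfg["coefficient"]),
                              exponent=int(cfg["exponent"]))
    if kind == "linear":
        return ConstantRateFamily(stiffness=float(cfg["a1"]))
    raise ValueError(f"unknown family type {kind!r}")


@dataclass
class RunConfig:
    """Serializable description of a full analysis run.

    Sections: ``bond`` (xb nm, koff_th 1/s, kbt pN nm), ``protocol``
    (see :func:`protocol_from_config`), ``simulate`` (n, seed),
    ``spectrum`` (sigma pN, grid points), ``fit`` (max_iter, tolerances),
    ``study`` (velocities, sample_sizes, iterations, seed).  Round-trips
    losslessly through YAML.
    """

    bond: dict = field(default_factory=lambda: {
        "xb": 0.70, "koff_th": 1e-4, "kbt": DEFAULT_KBT})
    protocol: dict = field(default_factory=lambda: {
        "type": "wlc", "lp": 3.0, "lc": 10.0, "v": 0.01})
    simulate: dict = field(default_factory=lambda: {"n": 50, "seed": 0})
    spectrum: dict = field(default_factory=lambda: {"sigma": 3.0, "num": 2048})
    fit: dict = field(default_factory=dict)
    study: dict = field(default_factory=lambda: {
        "velocities": [0.01, 0.1, 1.0, 10.0],
        "sample_sizes": [50, 300],
        "iterations": 100,
        "sigma": 3.0,
        "seed": 0,
    })

    def bond_parameters(self) -> BondParameters:
        b = self.bond
        return BondParameters(xb=float(b["xb"]), koff_th=float(b["koff_th"]),
                              kbt=float(b.get("kbt", DEFAULT_KBT)))

    def make_protocol(self) -> LoadingProtocol:
        return protocol_from_config(self.protocol)

    def make_family(self) -> ProtocolFamily:
        cfg = {k: v for k, v in self.protocol.items() if k != "v"}
        return family_from_config(cfg)

    def to_dict(self) -> dict:
        return {"bond": self.bond, "protocol": self.protocol,
                "simulate": self.simulate, "spectrum": self.spectrum,
                "fit": self.fit, "study": self.study}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        base = cls()
        for section in ("bond", "protocol", "simulate", "spectrum",
                        "fit", "study"):
            if section in d:
                setattr(base, section, dict(d[section]))
        return base

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def generate_fixtures(outdir, config: RunConfig | None = None,
                      seed: int | None = None) -> list[Path]:
    """Write a complete synthetic input set for offline analysis runs.

    Produces, deterministically under the master seed:

    * ``wlc_curve.txt`` -- a tabulated WLC force--distance curve (200
      nodes) usable as an empirical protocol;
    * ``ruptures_v<v>_n<N>.txt`` -- rupture-force datasets for each study
      velocity at N in {50, 300};
    * ``velocity_peaks.txt`` -- the analytic (velocity, peak force)
      table from the implicit-relation predictor;
    * ``config.yaml`` -- the configuration that regenerates everything.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or RunConfig()
    if seed is None:
        seed = int(cfg.study.get("seed", 0))
    params = cfg.bond_parameters()
    family = cfg.make_family()
    velocities = [float(v) for v in cfg.study["velocities"]]
    written: list[Path] = []

    if isinstance(family, WLCFamily):
        proto0 = family.protocol(velocities[0])
        L = np.linspace(0.0, family.Lc * 0.999, 200)
        F = np.asarray(proto0.force(L / velocities[0]))
        p = outdir / "wlc_curve.txt"
        write_force_distance(p, L, F, meta={"lp_nm": family.lp,
                                            "Lc_um": family.Lc,
                                            "kbt_pN_nm": family.kbt})
        written.append(p)

    ss = np.random.SeedSequence(seed)
    for N in (50, 300):
        for v, child in zip(velocities, ss.spawn(len(velocities))):
            model = RuptureModel(params, family.protocol(v))
            rng = np.random.default_rng(child)
            forces = model.sample_forces(N, rng)
            ds = RuptureDataset(forces=forces, velocity=v,
                                protocol=family.protocol(v).describe(),
                                params=params, seed=seed)
            p = outdir / f"ruptures_v{v:g}_n{N}.txt"
            write_rupture_forces(p, ds)
            written.append(p)

    peaks = predict_peak_forces(params, family, velocities)
    pairs = [VelocityPeakPair(v=v, f_star=f)
             for v, f in zip(velocities, peaks)]
    p = outdir / "velocity_peaks.txt"
    write_velocity_peaks(p, pairs, meta={"source": "analytic predictor",
                                         "bond": {"xb_nm": params.xb,
                                                  "koff_th_per_s": params.koff_th}})
    written.append(p)

    p = outdir / "config.yaml"
    cfg.save(p)
    written.append(p)
    return written
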