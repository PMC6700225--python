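"""Readers/writers for profiles, configs and flux records, plus run manifests.

All tabular outputs are TSV with a fixed column order and floats at 12
significant digits, so repeated runs with the same seed produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import yaml

from .engine import FluxRecord, GlycanProfile, GolgiConfig
from .glycans import GlycanState, classify, composition
from .rules import ENZYMES

_FLOAT_FMT = "{:.12g}"


class ProfileNormalizationError(ValueError):
    pass


def write_profile(profile: GlycanProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("state_code\tcomposition\tglycan_class\tabundance\n")
        for code in sorted(profile.abundance):
            state = GlycanState.from_code(code)
            fh.write(
                f"{code}\t{composition(state)}\t{classify(state).category}\t"
                f"{_FLOAT_FMT.format(profile.abundance[code])}\n"
            )


def read_profile(path) -> GlycanProfile:
    abundance: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:1] != ["state_code"] or "abundance" not in header:
            raise ValueError(f"{path}: unrecognized profile header")
        a_col = header.index("abundance")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} columns")
            try:
                abundance[parts[0]] = float(parts[a_col])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad abundance") from exc
    total = sum(abundance.values())
    err = abs(total - 1.0)
    if err > 1e-3:
        raise ProfileNormalizationError(
            f"{path}: abundances sum to {total:.6f}, beyond tolerance"
        )
    if err > 1e-9:
        import warnings

        warnings.warn(f"{path}: renormalizing profile (sum was {total:.6f})")
        abundance = {k: v / total for k, v in abundance.items()}
    return GlycanProfile(abundance=abundance)


def write_config(config: GolgiConfig, path) -> None:
    doc = {
        "n_cisternae": config.n_cisternae,
        "residence_times": [float(t) for t in config.residence_times],
        "rates": {e: [float(r) for r in config.rates[e]] for e in ENZYMES},
        "entry_mix": {k: float(v) for k, v in sorted(config.entry_mix.items())},
        "n_glycans": config.n_glycans,
        "seed": config.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_config(path) -> GolgiConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: config must be a mapping")
    required = {"n_cisternae", "residence_times", "rates", "entry_mix"}
    missing = required - doc.keys()
    if missing:
        raise ValueError(f"{path}: missing config fields: {sorted(missing)}")
    unknown = [e for e in doc["rates"] if e not in ENZYMES]
    if unknown:
        raise ValueError(f"{path}: unknown enzyme in rates: {unknown[0]!r}")
    try:
        return GolgiConfig(
            n_cisternae=int(doc["n_cisternae"]),
            residence_times=tuple(doc["residence_times"]),
            rates={e: tuple(v) for e, v in doc["rates"].items()},
            entry_mix=dict(doc["entry_mix"]),
            n_glycans=int(doc.get("n_glycans", 10000)),
            seed=int(doc.get("seed", 0)),
        )
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid config: {exc}") from exc


def write_flux(flux: FluxRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write("enzyme\tsubstrate_code\tcisterna\tcount\n")
        for (enzyme, sub, cist), k in sorted(flux.counts.items()):
            fh.write(f"{enzyme}\t{sub}\t{cist}\t{k}\n")


def read_flux(path) -> FluxRecord:
    flux = FluxRecord()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["enzyme", "substrate_code", "cisterna", "count"]:
            raise ValueError(f"{path}: unrecognized flux header")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            enzyme, sub, cist, count = parts
            if enzyme not in ENZYMES:
                raise ValueError(f"{path}:{lineno}: unknown enzyme {enzyme!r}")
            GlycanState.from_code(sub)
            flux.counts[(enzyme, sub, int(cist))] = int(count)
    return flux


def config_hash(config: GolgiConfig) -> str:
    doc = {
        "n_cisternae": config.n_cisternae,
        "residence_times": list(config.residence_times),
        "rates": {e: list(config.rates[e]) for e in ENZYMES},
        "entry_mix": dict(sorted(config.entry_mix.items())),
        "n_glycans": config.n_glycans,
    }
    blob = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, config: GolgiConfig, seeds: list[int], outputs: list[str]) -> dict:
    from . import __version__

    manifest = {
        "config_hash": config_hash(config),
        "seeds": list(seeds),
        "tool_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": [str(Path(o).name) for o in outputs],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
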