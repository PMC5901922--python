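"""Deterministic fixture emitter: the default config, the 20-run grid
manifest, and the four named pH-gate parameterizations."""

from __future__ import annotations

from pathlib import Path

from .config import (GatingParams, ModelParameters, experiment_grid,
                     write_config)

#: Named pH-gate parameterizations (alpha, n) spanning the gating family.
GATING_PRESETS: dict[str, tuple[float, float]] = {
    "gate_steep": (1e5, 6),
    "gate_sharp": (1e4, 5),
    "gate_default": (1.2e3, 4),
    "gate_soft": (1e3, 4),
}


def make_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the base config, grid manifest and gating presets; byte-stable."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    params = ModelParameters()
    base = out / "default.toml"
    write_config(params, base)
    written.append(base)

    manifest = out / "grid_manifest.json"
    manifest.write_text(experiment_grid(params).to_json() + "\n")
    written.append(manifest)

    for name, (alpha, n) in GATING_PRESETS.items():
        preset = params.model_copy(update={
            "gating": GatingParams(alpha=alpha, n_exponent=n,
                                   n_ptp=params.gating.n_ptp)})
        path = out / f"{name}.toml"
        write_config(preset, path)
        written.append(path)
    return written
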