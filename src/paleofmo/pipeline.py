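"""Config-driven end-to-end runs: reconstruction, funnel, reports, manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import asr, evomodel, funnel as funnel_mod
from .formats import (
    Alignment,
    coordinate_map_from_mask,
    read_annotations,
    read_fasta,
    read_newick,
    write_fasta,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated settings for one pipeline run.

    Thresholds default to the reconstruction-funnel conventions this
    package implements: MAP posterior > 0.8 for a confident state, second
    state > 0.2 for ambiguity, modal frequency >= 0.8 for conservation.
    """

    alignment: str
    tree: str
    nodes: list[str]
    out_dir: str
    matrix: str = "JTT"
    frequencies_mode: str = "matrix_default"
    alpha: float = 1.114
    categories: int = 4
    pp_true: float = 0.8
    pp_ambiguous: float = 0.2
    conservation_threshold: float = 0.8
    annotations: str | None = None
    funnel_parent: str | None = None
    funnel_child: str | None = None
    sn_clade: list[str] = field(default_factory=list)
    bv_clade: list[str] = field(default_factory=list)
    explicit_sets: dict = field(default_factory=dict)
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = [k for k in ("alignment", "tree", "nodes", "out_dir") if k not in raw]
        if missing:
            raise ConfigError(f"missing required config keys: {missing}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("pp_true", "pp_ambiguous", "conservation_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} = {v} outside [0, 1]")
        if self.alpha <= 0:
            raise ConfigError(f"alpha must be positive, got {self.alpha}")
        if self.categories < 1:
            raise ConfigError(f"categories must be >= 1, got {self.categories}")
        if not self.nodes:
            raise ConfigError("no target nodes given")
        if (self.funnel_parent is None) != (self.funnel_child is None):
            raise ConfigError("funnel needs both funnel_parent and funnel_child")
        if self.funnel_parent is not None:
            for n in (self.funnel_parent, self.funnel_child):
                if n not in self.nodes:
                    raise ConfigError(f"funnel node {n!r} not among target nodes")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_per_site_table(profile, mask, coord_map, path) -> None:
    """Bit-stable per-site TSV: fixed column order, six-decimal posteriors."""
    with open(path, "w") as fh:
        fh.write("column\tresidue_pos\tMAP\tPP_MAP\talt\tPP_alt\tambiguous\tpresent\n")
        for i in range(profile.n_sites):
            col = i + 1
            res = coord_map.residue(col)
            fh.write(
                f"{col}\t{res if res is not None else ''}\t"
                f"{profile.map_state[i]}\t{profile.pp_map[i]:.6f}\t"
                f"{profile.alt_state[i]}\t{profile.pp_alt[i]:.6f}\t"
                f"{int(profile.ambiguous[i])}\t{int(mask.present[i])}\n"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Execute reconstruction (and optionally the funnel) per the config.

    Writes, per target node, a FASTA with the MAP and AltAll ancestors and a
    per-site TSV; optionally a funnel TSV and summary; and a manifest with
    input hashes, settings and per-stage counts.  Returns the manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    try:
        alignment = read_fasta(config.alignment)
        tree = read_newick(config.tree)
        annotations = (
            read_annotations(config.annotations) if config.annotations else {}
        )
        stage = "build_model"
        model = evomodel.build_model(
            matrix_name=config.matrix,
            frequencies_mode=config.frequencies_mode,
            alpha=config.alpha,
            K=config.categories,
            alignment=alignment,
        )
        manifest = {
            "inputs": {
                "alignment": {"path": str(config.alignment), "sha256": _sha256(config.alignment)},
                "tree": {"path": str(config.tree), "sha256": _sha256(config.tree)},
            },
            "settings": config.to_dict(),
            "nodes": {},
        }
        if config.annotations:
            manifest["inputs"]["annotations"] = {
                "path": str(config.annotations),
                "sha256": _sha256(config.annotations),
            }

        profiles, masks = {}, {}
        for node in config.nodes:
            stage = f"asr:{node}"
            profile = asr.marginal_posteriors(alignment, tree, model, node)
            mask = asr.fitch_gap_mask(alignment, tree, node)
            profiles[node], masks[node] = profile, mask
            map_seq = asr.map_sequence(profile, mask)
            alt_seq = asr.altall_sequence(
                profile, mask, threshold=config.pp_ambiguous
            )
            node_aln = Alignment([f"{node}_MAP", f"{node}_AltAll"], [map_seq, alt_seq])
            write_fasta(node_aln, out / f"{node}.fasta")
            cmap = coordinate_map_from_mask(node, mask.present)
            write_per_site_table(profile, mask, cmap, out / f"{node}_sites.tsv")
            manifest["nodes"][node] = {
                "length": len(map_seq),
                "mean_pp": round(asr.mean_pp(profile, mask), 6),
                "ambiguous_sites": int(profile.ambiguous[mask.present].sum()),
            }
            logger.info(
                "node %s: length %d, mean PP %.4f",
                node, len(map_seq), manifest["nodes"][node]["mean_pp"],
            )

        if config.funnel_parent is not None:
            stage = "funnel"
            parent, child = config.funnel_parent, config.funnel_child
            cmap = coordinate_map_from_mask(child, masks[child].present)
            records = funnel_mod.enumerate_substitutions(
                profiles[parent], profiles[child],
                masks[parent], masks[child], cmap,
            )
            prof_all = funnel_mod.conservation_profile(
                alignment, alignment.ids,
                threshold=config.conservation_threshold, clade_name="all",
            )
            prof_sn = funnel_mod.conservation_profile(
                alignment, config.sn_clade or alignment.ids,
                threshold=config.conservation_threshold, clade_name="SN",
            )
            prof_bv = funnel_mod.conservation_profile(
                alignment, config.bv_clade or alignment.ids,
                threshold=config.conservation_threshold, clade_name="BV",
            )
            result = funnel_mod.apply_funnel(
                records, prof_all, prof_sn, prof_bv, annotations,
                pp_true=config.pp_true, pp_alt=config.pp_ambiguous,
            )
            sets = funnel_mod.compose_mutant_sets(
                result.survivors,
                explicit={k: list(v) for k, v in config.explicit_sets.items()},
            )
            _write_funnel_table(result, out / "funnel.tsv")
            manifest["funnel"] = {
                "branch": f"{parent} -> {child}",
                "counts": result.counts,
                "sets": {name: sorted(r.position for r in recs)
                         for name, recs in sets.items()},
            }

        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _write_funnel_table(result, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "position\tcolumn\tparent_state\tparent_pp\tchild_state\tchild_pp\t"
            "pp_class\tconservation\tcategory\tlocation\tsets\tdropped_at\n"
        )
        for rec in sorted(result.records, key=lambda r: r.position):
            fh.write(
                f"{rec.position}\t{rec.column}\t{rec.parent_state}\t"
                f"{rec.parent_pp:.6f}\t{rec.child_state}\t{rec.child_pp:.6f}\t"
                f"{rec.pp_class or ''}\t{rec.conservation or ''}\t"
                f"{rec.category or ''}\t{rec.location or ''}\t"
                f"{','.join(sorted(rec.sets))}\t{rec.dropped_at or ''}\n"
            )
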