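"""End-to-end driver: build fixtures, assemble, score, run topology, report.

The configuration is a small YAML document; all bp coordinates in the file
are 1-based (footprinting convention) and converted to 0-based indices
internally.  A run is deterministic given the configuration: the report
carries every configured value plus the seed, and every reported number is
recomputable from the emitted model files.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import constraints as cns
from . import docking as dk
from . import synthetic as syn
from . import topology as tp
from .dna import EnhancerLayout
from .structure import AtomSet, AtomRecord, write_structure

__all__ = ["RunReport", "load_config", "validate", "run", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "enhancer": {
        "total_bp": 65,
        "site_block_bp": 21,
        "core_bp": 15,
        "center_separation_bp": 47,
        "site1_center": 10,   # 1-based
        "site2_center": 57,
        "fis_bend_deg": 65.0,
    },
    "substrate": {"loop_bp": 99, "plasmid_bp": 2300},
    "assembly": {"state": "cleaved", "contact_cutoff": 6.0,
                 "basic_patch_cutoff": 7.0},
    "febabe": {"tether_length": 12.0, "radical_radius": 10.0},
    "rotations": 4,
}


@dataclass
class RunReport:
    """Machine-readable summary of one pipeline run."""

    config: dict
    state: str
    crosslinks: list = field(default_factory=list)
    footprints: dict = field(default_factory=dict)
    node_count: int = 0
    node_signs: list = field(default_factory=list)
    delta_lk: dict = field(default_factory=dict)
    knot_determinants: dict = field(default_factory=dict)
    basic_patch: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def _merged(cfg: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def validate(cfg: dict) -> list[str]:
    """Schema and invariant checks; returns a list of diagnostics."""
    diags: list[str] = []
    cfg = _merged(cfg)
    enh = cfg.get("enhancer", {})
    required = ("total_bp", "site_block_bp", "core_bp",
                "center_separation_bp", "site1_center", "site2_center")
    for key in required:
        if key not in enh:
            diags.append(f"enhancer section missing {key}")
    if not diags:
        c1, c2 = enh["site1_center"] - 1, enh["site2_center"] - 1
        if abs(c2 - c1) != enh["center_separation_bp"]:
            diags.append("center_separation_bp inconsistent with site centers")
        try:
            EnhancerLayout(total_bp=enh["total_bp"],
                           site_block_bp=enh["site_block_bp"],
                           core_bp=enh["core_bp"],
                           center_separation_bp=enh["center_separation_bp"],
                           site1_center_index=c1, site2_center_index=c2)
        except ValueError as exc:
            diags.append(f"enhancer layout invalid: {exc}")
        bend = enh.get("fis_bend_deg", 65.0)
        if not 0 <= bend < 180:
            diags.append("fis_bend_deg out of range [0, 180)")
    sub = cfg.get("substrate", {})
    if sub.get("loop_bp", 99) <= 0:
        diags.append("negative or zero loop length")
    elif sub.get("loop_bp", 99) >= sub.get("plasmid_bp", 2300):
        diags.append("loop length exceeds plasmid size")
    state = cfg.get("assembly", {}).get("state", "cleaved")
    if state not in dk.ASSEMBLY_STATES:
        diags.append(f"unknown assembly state {state!r}")
    if cfg.get("rotations", 0) < 0:
        diags.append("rotations must be >= 0")
    return diags


def _layout_from(cfg: dict) -> tuple[EnhancerLayout, float]:
    enh = cfg["enhancer"]
    lay = EnhancerLayout(total_bp=enh["total_bp"],
                         site_block_bp=enh["site_block_bp"],
                         core_bp=enh["core_bp"],
                         center_separation_bp=enh["center_separation_bp"],
                         site1_center_index=enh["site1_center"] - 1,
                         site2_center_index=enh["site2_center"] - 1)
    return lay, float(enh.get("fis_bend_deg", 65.0))


def _merge_components(asm: dk.Assembly) -> AtomSet:
    """All placed components as one multi-chain AtomSet for PDB export."""
    chain_ids = iter("ABCDEFGHIJKLMNOP")
    records: list[AtomRecord] = []
    for name in sorted(asm.components):
        comp = asm.components[name]
        remap: dict[str, str] = {}
        for rec in comp.records:
            if rec.chain not in remap:
                remap[rec.chain] = next(chain_ids)
            records.append(AtomRecord(chain=remap[rec.chain],
                                      resseq=rec.resseq, resname=rec.resname,
                                      name=rec.name, element=rec.element,
                                      xyz=rec.xyz))
    return AtomSet(tuple(records))


def run(cfg: dict, outdir: str | Path) -> RunReport:
    """Execute the full pipeline and write artifacts into ``outdir``."""
    diags = validate(cfg)
    if diags:
        raise ValueError("invalid configuration: " + "; ".join(diags))
    cfg = _merged(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    lay, bend = _layout_from(cfg)
    spec = syn.FixtureSpec(seed=int(cfg.get("seed", 0)), fis_bend=bend,
                           layout=lay,
                           loop_bp=cfg["substrate"]["loop_bp"],
                           plasmid_bp=cfg["substrate"]["plasmid_bp"])
    enh_model = syn.make_enhancer_model(spec)
    state = cfg["assembly"]["state"]
    components = syn.make_toy_components(spec, state)
    acfg = dk.AssemblyConfig(enhancer=enh_model, layout=lay,
                             components=components,
                             contact_cutoff=cfg["assembly"]["contact_cutoff"],
                             loop_bp=spec.loop_bp)
    asm = dk.assemble_invertasome(acfg, state)
    (out / f"assembly_{state}.pdb").write_text(
        write_structure(_merge_components(asm)))

    report = RunReport(config=cfg, state=state)
    report.crosslinks = cns.score_crosslink_set(
        asm, cns.packaged_crosslink_set())
    reach = cns.FeBABEReach(**cfg["febabe"])
    for tether in ("hin_hix1L.H.54", "hin_hix2R.H.54", "fis1.A.98",
                   "fis2.A.98"):
        preds = cns.predict_febabe_footprint(asm, tether, reach)
        report.footprints[tether] = [[p.bp, p.strand, p.distance]
                                     for p in preds]
        (out / f"footprint_{tether.replace('.', '_')}.bed").write_text(
            cns.footprint_to_bed(preds))
    patch_cut = cfg["assembly"].get("basic_patch_cutoff", 7.0)
    for sub in sorted(k for k in asm.components if k.startswith("hin_")):
        report.basic_patch[sub] = cns.basic_patch_contacts(
            asm, sub, "enhancer", patch_cut)

    # topology on the synthetic substrate
    sub_geom = syn.make_substrate_geometry(spec)
    (out / "substrate_curve.txt").write_text(tp.write_curve(sub_geom.curve))
    nodes = tp.count_nodes(sub_geom.curve, tp.NODE_PROJECTION,
                           "hix", "enhancer")
    report.node_count = len(nodes)
    report.node_signs = [int(s) for _, s in nodes]
    for n in range(0, int(cfg["rotations"]) + 1):
        product = tp.simulate_rotation(sub_geom, n)
        report.delta_lk[str(n)] = tp.delta_linking(sub_geom, product)
        report.knot_determinants[str(n)] = tp.knot_determinant(product.curve)
        if n in (0, 1):
            (out / f"product_n{n}.txt").write_text(
                tp.write_curve(product.curve))

    (out / "report.json").write_text(report.to_json())
    return report
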