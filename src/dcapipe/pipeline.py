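"""End-to-end orchestration: config, staged execution, reproducible outputs.

A run goes msa -> potts -> structures -> topology, reading either real
inputs (FASTA + PDB paths) or a named synthetic scenario.  Every output
file carries the seed and a hash of the resolved configuration, and a
repeated run with the same config and inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import msa as msa_mod
from . import potts as potts_mod
from . import structures as struct_mod
from . import synth as synth_mod
from . import topology as topo_mod


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class StructureInput:
    path: str
    chains: list[str] = field(default_factory=lambda: ["A"])
    name: str = ""


@dataclass
class RunConfig:
    """All pipeline settings, defaulting to the reference analysis values:
    gap filter 0.25, identity filter 0.90, lambda_h = lambda_J = 0.01,
    n_top 624 at separation >= 5, contact threshold 8.5 Å."""

    # inputs: either a file-based family ...
    msa_path: str | None = None
    taxon_path: str | None = None
    structures: list[StructureInput] = field(default_factory=list)
    ref_row: str | None = None  # id of the MSA row used for backmapping
    # ... or a synthetic scenario
    scenario: str | None = None  # "two_state" | "clade"
    scenario_params: dict = field(default_factory=dict)

    # filtering
    max_gap_fraction: float = 0.25
    max_identity: float = 0.90
    gap_filter_first: bool = True

    # model
    lambda_h: float = 0.01
    lambda_J: float = 0.01
    tol: float = 1e-5

    # predictions
    n_top: int = 624
    min_sep: int = 5

    # structures
    contact_threshold: float = 8.5

    # sweep
    we_grid: list[float] = field(default_factory=list)

    seed: int = 0
    out_dir: str = "run_out"

    def validate(self) -> None:
        if not 0 <= self.max_gap_fraction <= 1:
            raise ValueError("max_gap_fraction must lie in [0, 1]")
        if not 0 < self.max_identity <= 1:
            raise ValueError("max_identity must lie in (0, 1]")
        if self.n_top < 1 or self.min_sep < 0:
            raise ValueError("n_top >= 1 and min_sep >= 0 required")
        if self.contact_threshold <= 0:
            raise ValueError("contact_threshold must be positive")
        if any(not 0 <= w <= 1 for w in self.we_grid):
            raise ValueError("W_E grid values must lie in [0, 1]")
        if self.msa_path is None and self.scenario is None:
            raise ValueError("either msa_path or scenario must be given")

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        structures = [
            StructureInput(**s) if isinstance(s, dict) else StructureInput(path=s)
            for s in raw.pop("structures", [])
        ]
        return cls(structures=structures, **raw)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # the hash identifies the analysis, not its destination
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class Run:
    """Executes a :class:`RunConfig` and writes the report files."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.cfg = config
        self.out = Path(config.out_dir)
        self.log_lines: list[str] = []
        self._t0 = time.time()

    def log(self, msg: str) -> None:
        self.log_lines.append(f"[{time.time() - self._t0:8.2f}s] {msg}")

    def header(self) -> str:
        return f"# dcapipe run, seed={self.cfg.seed}, config={self.cfg.config_hash()}\n"

    def execute(self) -> Path:
        self.out.mkdir(parents=True, exist_ok=True)
        try:
            aln, scenario = self._stage_msa()
        except StageError:
            raise
        except Exception as e:
            raise StageError("msa", str(e)) from e
        try:
            scores, preds = self._stage_potts(aln)
        except Exception as e:
            raise StageError("potts", str(e)) from e
        try:
            maps, interface_cols = self._stage_structures(aln, scenario)
        except StageError:
            raise
        except Exception as e:
            raise StageError("structures", str(e)) from e
        try:
            self._stage_topology(aln, scores, preds, maps, interface_cols, scenario)
        except Exception as e:
            raise StageError("topology", str(e)) from e
        with open(self.out / "log.txt", "w") as fh:
            fh.write(self.header())
            fh.write("\n".join(self.log_lines) + "\n")
        return self.out

    # -- stages ------------------------------------------------------------

    def _stage_msa(self):
        cfg = self.cfg
        scenario = None
        if cfg.scenario is not None:
            scenario, aln = self._build_scenario()
            self.log(f"scenario {cfg.scenario}: M={aln.M}, L={aln.L}")
        else:
            aln = msa_mod.read_alignment(cfg.msa_path, taxon_path=cfg.taxon_path)
            self.log(f"read {cfg.msa_path}: M={aln.M}, L={aln.L}")
        steps = [
            ("gap", lambda a: msa_mod.filter_by_gap_fraction(a, cfg.max_gap_fraction)),
            ("identity", lambda a: msa_mod.filter_by_identity(a, cfg.max_identity)),
        ]
        if not cfg.gap_filter_first:
            steps.reverse()
        for name, fn in steps:
            before = aln.M
            aln = fn(aln)
            self.log(f"{name} filter: M {before} -> {aln.M}")
        msa_mod.write_alignment(aln, self.out / "filtered.fasta")
        if aln.taxon is not None:
            msa_mod.write_taxon_table(aln, self.out / "taxon.tsv")
        return aln, scenario

    def _build_scenario(self):
        cfg = self.cfg
        params = dict(cfg.scenario_params)
        M = params.pop("M", 5000)
        if cfg.scenario == "two_state":
            sc = synth_mod.two_state_scenario(seed=cfg.seed, **params)
            aln = synth_mod.gibbs_sample(sc.model, M, seed=cfg.seed + 1)
        elif cfg.scenario == "clade":
            params.setdefault("M_per_clade", M // 2)
            sc, aln = synth_mod.clade_scenario(seed=cfg.seed, **params)
        else:
            raise ValueError(f"unknown scenario {cfg.scenario!r}")
        return sc, aln

    def _stage_potts(self, aln):
        cfg = self.cfg
        w = msa_mod.SequenceWeights.uniform(aln.M)
        model = potts_mod.fit_plm(
            aln, w, lambda_h=cfg.lambda_h, lambda_J=cfg.lambda_J, tol=cfg.tol
        )
        self.log(f"PLM fit done (M_eff={w.M_eff:.1f}, lambda_h={cfg.lambda_h}, "
                 f"lambda_J={cfg.lambda_J}, tol={cfg.tol})")
        scores = potts_mod.apc(potts_mod.frobenius_scores(model))
        n_top = min(cfg.n_top, len(potts_mod.eligible_pairs(aln.L, cfg.min_sep)))
        preds = potts_mod.rank_predictions(scores, n_top=n_top, min_sep=cfg.min_sep)
        self._write_with_header(
            potts_mod.write_scores, scores, self.out / "scores.tsv"
        )
        self._write_with_header(
            potts_mod.write_predictions, preds, self.out / "predictions.tsv"
        )
        self.log(f"ranked top {preds.n} predictions at min_sep={cfg.min_sep}")
        return scores, preds

    def _stage_structures(self, aln, scenario):
        cfg = self.cfg
        maps: dict[str, struct_mod.ContactMap] = {}
        interface_cols: list[tuple[int, int]] = []
        if scenario is not None:
            maps = dict(scenario.maps)
            interface_cols = list(scenario.interface)
            self.log(f"scenario maps: {sorted(maps)}")
            return maps, interface_cols
        if not self.cfg.structures:
            self.log("no structures given; skipping backmapping")
            return maps, interface_cols
        ref_idx = 0
        if cfg.ref_row is not None:
            if cfg.ref_row not in aln.ids:
                raise StageError("structures", f"ref_row {cfg.ref_row!r} not in the filtered MSA")
            ref_idx = aln.ids.index(cfg.ref_row)
        ref = aln.rows[ref_idx]
        for spec in cfg.structures:
            if not Path(spec.path).exists():
                raise StageError("structures", f"structure file not found: {spec.path}")
            chains = struct_mod.read_structure(spec.path, spec.chains)
            name = spec.name or Path(spec.path).stem
            mappings = []
            for ch in chains:
                cm_res = struct_mod.contact_map(ch, cfg.contact_threshold)
                mapping = struct_mod.map_columns(ref, ch)
                mappings.append(mapping)
                cm_col = struct_mod.project_map(cm_res, mapping, aln.L)
                key = f"{name}_{ch.chain_id}" if len(chains) > 1 else name
                maps[key] = cm_col
                self.log(f"{key}: {ch.n_residues} residues, "
                         f"{cm_col.n_contacts()} contacts, identity {mapping.identity:.3f}")
            if len(chains) == 2:
                iface = struct_mod.interface_contacts(
                    chains[0], chains[1], cfg.contact_threshold,
                    mappings[0], mappings[1],
                )
                interface_cols = list(iface.column_pairs)
                self.log(f"{name} interface: K = {iface.K} residue pairs")
        if len(maps) >= 2:
            names = list(maps)
            maps["union"] = struct_mod.union_map(maps[names[0]], maps[names[1]])
        for key, cm in maps.items():
            self._write_with_header(
                struct_mod.write_contact_map, cm, self.out / f"map_{key}.tsv"
            )
        return maps, interface_cols

    def _stage_topology(self, aln, scores, preds, maps, interface_cols, scenario):
        cfg = self.cfg
        named_annos = {}
        summaries = {}
        for key, cm in maps.items():
            annos, summary = topo_mod.annotate(preds, cm)
            named_annos[key] = annos
            summaries[key] = summary
            self.log(f"map {key}: TP {summary.tp_count}/{summary.n} "
                     f"({summary.tp_rate:.1%}; mapped-only {summary.tp_rate_mapped:.1%})")
        if {"A", "B"} <= set(named_annos):
            named_annos["minSP_AB"] = topo_mod.union_sp(named_annos["A"], named_annos["B"])
            summaries["minSP_AB"] = topo_mod.summarize(named_annos["minSP_AB"])
        if named_annos:
            topo_mod.write_annotations(
                self.out / "annotations.tsv", preds, named_annos, interface_cols
            )

        blocks: dict[str, dict] = {"run": {"seed": cfg.seed, "config": cfg.config_hash(),
                                           "M": aln.M, "L": aln.L, "n_top": preds.n}}
        for key, s in summaries.items():
            blocks[f"map_{key}"] = {
                "tp_count": s.tp_count, "tp_rate": round(s.tp_rate, 6),
                "tp_rate_mapped": round(s.tp_rate_mapped, 6),
                "n_unmapped": s.n_unmapped,
                "sp_histogram": json.dumps(s.sp_histogram, sort_keys=True),
            }
        if interface_cols:
            hits = [p for p in ((i, j) for i, j, _ in preds) if p in set(interface_cols)]
            N_all = aln.L * (aln.L - 1) // 2
            N_sep = len(potts_mod.eligible_pairs(aln.L, cfg.min_sep))
            test = topo_mod.hypergeom_upper_tail(preds.n, len(hits), N_all, len(interface_cols))
            test_sep = topo_mod.hypergeom_upper_tail(preds.n, len(hits), N_sep, len(interface_cols))
            blocks["enrichment"] = {
                "n": test.n, "k": test.k, "K": test.K,
                "N_all_pairs": test.N, "P_all_pairs": f"{test.P_k:.6g}",
                "N_sep_filtered": test_sep.N, "P_sep_filtered": f"{test_sep.P_k:.6g}",
            }
            self.log(f"interface enrichment: k={test.k}/{test.K}, P={test.P_k:.3g}")
        if cfg.we_grid:
            if aln.taxon is None:
                raise ValueError("W_E sweep requires taxon labels")
            ref_map = maps.get("union") or next(iter(maps.values()))
            points = topo_mod.weight_sweep(
                aln, cfg.we_grid, interface_cols, ref_map,
                n_top=preds.n, min_sep=cfg.min_sep,
                lambda_h=cfg.lambda_h, lambda_J=cfg.lambda_J, tol=cfg.tol,
                reference_top_pairs=[(i, j) for i, j, _ in preds],
            )
            blocks["sweep"] = {
                f"W_E_{p.W_E:g}": f"strength={p.relative_strength:.4f}"
                                  f",tp_rate={p.tp_rate:.4f},M_eff={p.M_eff:.1f}"
                for p in points
            }
            for p in points:
                self.log(f"sweep W_E={p.W_E:g}: strength {p.relative_strength:.3f}, "
                         f"tp {p.tp_rate:.1%}")
        topo_mod.write_summary(self.out / "summary.tsv", blocks)

    def _write_with_header(self, writer, obj, path) -> None:
        writer(obj, path)
        text = Path(path).read_text()
        Path(path).write_text(self.header() + text)


def run(config: RunConfig) -> Path:
    """Execute the full pipeline for ``config``; returns the run directory."""
    return Run(config).execute()
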