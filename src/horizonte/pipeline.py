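"""End-to-end orchestration: config-driven runs with a reproducible manifest.

A run executes, per configured taxon, the synthetic (or file-based)
amplification inputs -> consensus -> per-copy divergence -> landscape ->
activity dating chain, then the wave test between two groups of taxa, a
reconciliation stage and a biogeography stage.  Every output file is
recorded in a JSON manifest with its SHA-256 checksum; identical configs
produce byte-identical outputs (all randomness flows from the run seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .biogeography import (DEFAULT_AREAS, diva_reconstruct, read_leaf_areas,
                           write_reconstruction_tsv)
from .consensus import build_consensus, write_support_table
from .divergence import alignment_divergences, write_divergence_table
from .errors import ConfigError
from .io_formats import (read_fasta, read_newick_file, write_fasta,
                         write_newick)
from .consensus import CopyAlignment
from .landscape import (RateSpec, build_landscape, estimate_activity,
                        wave_test, write_activity_table,
                        write_landscape_table)
from .reconciliation import min_transfers, write_reconciliation_tsv
from .simulate import (AmplificationParams, random_binary_tree,
                       simulate_amplification, simulate_areas,
                       simulate_transfers)

import numpy as np


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_yaml``)."""

    seed: int
    outdir: Path
    taxa: dict[str, dict[str, Any]]
    rates: dict[str, RateSpec]
    consensus: dict[str, Any] = field(default_factory=dict)
    divergence: dict[str, Any] = field(default_factory=dict)
    landscape: dict[str, Any] = field(default_factory=dict)
    waves: dict[str, list[str]] | None = None
    reconciliation: dict[str, Any] | None = None
    biogeography: dict[str, Any] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw, base=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any],
                  base: Path | None = None) -> "RunConfig":
        try:
            seed = int(raw.get("seed", 0))
            outdir = Path(raw["outdir"])
            taxa = dict(raw["taxa"])
        except KeyError as exc:
            raise ConfigError(f"missing required config key: {exc}") from exc
        rates = {}
        for taxon, spec in (raw.get("rates") or {}).items():
            rates[taxon] = RateSpec(
                value=float(spec["value"]),
                unit=spec.get("unit", "per_year"),
                generation_time_days=float(
                    spec.get("generation_time_days", 90.0)))
        for taxon, spec in taxa.items():
            if "copies" in spec and base is not None:
                spec["copies"] = str((base / spec["copies"]).resolve()) \
                    if not Path(spec["copies"]).is_absolute() \
                    else spec["copies"]
        return cls(seed=seed, outdir=outdir, taxa=taxa, rates=rates,
                   consensus=dict(raw.get("consensus") or {}),
                   divergence=dict(raw.get("divergence") or {}),
                   landscape=dict(raw.get("landscape") or {}),
                   waves=raw.get("waves"),
                   reconciliation=raw.get("reconciliation"),
                   biogeography=raw.get("biogeography"))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _taxon_seed(base_seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{base_seed}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns (and writes) the manifest.

    Stage errors are re-raised as :class:`ConfigError` naming the stage
    and the offending input.  Outputs are deterministic functions of the
    config, so re-running the same config reproduces every file
    byte-for-byte.
    """
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def emit(path: Path) -> Path:
        files.append(path)
        return path

    # ---- per-taxon chain -------------------------------------------------
    estimates = []
    invasion_dates: dict[str, float] = {}
    for taxon, spec in config.taxa.items():
        tdir = out / taxon
        tdir.mkdir(exist_ok=True)
        if "copies" in spec:  # file-based input (aligned FASTA)
            records = read_fasta(spec["copies"])
            aln = CopyAlignment.from_records(records)
            reference = None
        else:  # synthetic amplification
            params = AmplificationParams(
                master_length=int(spec.get("master_length", 1000)),
                window_start=float(spec.get("window_start", 20.0)),
                window_end=float(spec.get("window_end", 15.0)),
                n_copies=int(spec.get("n_copies", 200)),
                rate=config.rates.get(taxon, RateSpec(2.5e-9)),
                kappa=float(spec.get("kappa", 2.0)),
                cpg_multiplier=float(spec.get("cpg_multiplier", 1.0)),
                truncation_p=float(spec.get("truncation_p", 0.004)),
                seed=_taxon_seed(config.seed, taxon),
            )
            master, aln, truth = simulate_amplification(params)
            write_fasta([master], emit(tdir / "master.fasta"))
            write_fasta(aln.records(), emit(tdir / "copies.fasta"))
            reference = truth.master_final if \
                config.divergence.get("reference") == "master" else None

        cons = build_consensus(
            aln,
            min_depth=int(config.consensus.get("min_depth", 3)),
            majority_fraction=float(
                config.consensus.get("majority_fraction", 0.5)),
            name=f"{taxon}_consensus")
        write_fasta([cons.record], emit(tdir / "consensus.fasta"))
        write_support_table(cons, emit(tdir / "support.tsv"))

        if reference is None:
            # project copies onto retained consensus columns
            rows = tuple("".join(row[j] for j in cons.columns)
                         for row in aln.rows)
            proj = CopyAlignment(aln.copy_ids, rows)
            divs = alignment_divergences(
                proj, cons.record,
                cpg_mode=config.divergence.get("cpg_mode", "exclude"))
        else:
            divs = alignment_divergences(
                aln, reference,
                cpg_mode=config.divergence.get("cpg_mode", "exclude"))
        if not divs:
            raise ConfigError(f"divergence: no usable copies for {taxon!r}")
        write_divergence_table(divs, emit(tdir / "divergence.tsv"))

        land = build_landscape(
            divs, bin_width=float(config.landscape.get("bin_width", 0.01)),
            taxon=taxon)
        write_landscape_table(land, emit(tdir / "landscape.tsv"))

        if taxon not in config.rates:
            raise ConfigError(f"dating: no substitution rate configured "
                              f"for taxon {taxon!r}")
        est = estimate_activity(
            land, config.rates[taxon],
            coverage_min=float(config.landscape.get("coverage_min", 0.95)),
            coverage_max=float(config.landscape.get("coverage_max", 0.99)))
        estimates.append(est)
        invasion_dates[taxon] = est.invasion_min
    write_activity_table(estimates, emit(out / "activity.tsv"))

    # ---- wave test -------------------------------------------------------
    wave_result = None
    if config.waves:
        for key in ("group1", "group2"):
            if key not in config.waves:
                raise ConfigError(f"waves: missing {key!r}")
            for taxon in config.waves[key]:
                if taxon not in invasion_dates:
                    raise ConfigError(
                        f"waves: unknown taxon {taxon!r} in {key}")
        g1 = [invasion_dates[t] for t in config.waves["group1"]]
        g2 = [invasion_dates[t] for t in config.waves["group2"]]
        wave_result = wave_test(g1, g2)
        with open(emit(out / "waves.tsv"), "w") as fh:
            fh.write("statistic\tpvalue\tdf\tflavor\n")
            fh.write(f"{wave_result.statistic:.6f}\t"
                     f"{wave_result.pvalue:.6g}\t{wave_result.df:.4f}\t"
                     f"{wave_result.flavor}\n")

    # ---- reconciliation --------------------------------------------------
    rec_result = None
    if config.reconciliation:
        rc = config.reconciliation
        if "simulate" in rc:
            sim = rc["simulate"]
            rng = np.random.default_rng(_taxon_seed(config.seed, "host"))
            host = random_binary_tree(
                [f"H{i + 1}" for i in range(int(sim.get("n_leaves", 8)))],
                rng)
            te, host_map, _truth = simulate_transfers(
                host, int(sim.get("k", 3)),
                seed=_taxon_seed(config.seed, "transfers"))
        else:
            try:
                host = read_newick_file(rc["host_tree"])
                te = read_newick_file(rc["te_tree"])
            except KeyError as exc:
                raise ConfigError(
                    f"reconciliation: missing input {exc}") from exc
            host_map = {}
            for line in Path(rc["host_map"]).read_text().splitlines():
                if line.strip() and not line.startswith("#"):
                    a, b = line.split("\t")
                    host_map[a] = b
        (out / "host_tree.nwk").write_text(write_newick(host) + "\n")
        emit(out / "host_tree.nwk")
        (out / "te_tree.nwk").write_text(write_newick(te) + "\n")
        emit(out / "te_tree.nwk")
        rec_result = min_transfers(te, host, host_map)
        write_reconciliation_tsv(rec_result,
                                 emit(out / "reconciliation.tsv"))

    # ---- biogeography ----------------------------------------------------
    bio_result = None
    if config.biogeography:
        bg = config.biogeography
        universe = tuple(bg.get("universe", DEFAULT_AREAS))
        if "simulate" in bg:
            sim = bg["simulate"]
            rng = np.random.default_rng(_taxon_seed(config.seed, "areas"))
            atree = random_binary_tree(
                [f"L{i + 1}" for i in range(int(sim.get("n_leaves", 8)))],
                rng)
            assignment, _truth = simulate_areas(
                atree, universe, d=int(sim.get("d", 2)),
                seed=_taxon_seed(config.seed, "area_history"))
        else:
            try:
                atree = read_newick_file(bg["tree"])
                assignment = read_leaf_areas(bg["areas"], universe)
            except KeyError as exc:
                raise ConfigError(
                    f"biogeography: missing input {exc}") from exc
        (out / "area_tree.nwk").write_text(write_newick(atree) + "\n")
        emit(out / "area_tree.nwk")
        bio_result = diva_reconstruct(
            atree, assignment, max_areas=int(bg.get("max_areas", 2)),
            enforce_leaf_limit=bool(bg.get("enforce_leaf_limit", True)))
        write_reconstruction_tsv(bio_result, emit(out / "areas.tsv"))

    # ---- manifest --------------------------------------------------------
    manifest: dict[str, Any] = {
        "package": "horizonte",
        "version": __version__,
        "seed": config.seed,
        "outputs": {str(p.relative_to(out)): _sha256(p)
                    for p in sorted(files)},
        "results": {
            "invasion_min_myr": {t: round(v, 4)
                                 for t, v in invasion_dates.items()},
            "wave_pvalue": (round(wave_result.pvalue, 8)
                            if wave_result else None),
            "transfer_count": (rec_result.transfer_count
                               if rec_result else None),
            "diva_cost": bio_result.cost if bio_result else None,
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
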