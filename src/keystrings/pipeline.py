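"""End-to-end orchestration: proteomes -> CVs -> key sets -> trees -> reports.

The pipeline reads a flat ``key = value`` config (or an equivalent dict),
runs the full chain, and writes all artifacts plus a JSON manifest with
parameters, seeds and output checksums.  Outputs land in a temporary
directory that is promoted atomically on success, and reruns with an
identical config are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import shutil
import tempfile
from pathlib import Path

from . import io as kio
from .cv import cv_matrix, export_cv_tsv
from .keys import (
    KeySet,
    effective_subgroups,
    extract_broad_keys,
    extract_specific_keys,
    global_keys,
    sharing_table,
    summarize_sharing,
    write_keyset,
)
from .conservation import (
    accumulation_regions,
    conservativity_profile,
    map_keys,
    overlap_summary,
    regions_to_bed,
)
from .seqstats import MODES, composition_profile
from .simulate import concatenated_alignment, fixture, species_table_for
from .trees import (
    BootstrapPlan,
    bootstrap_trees,
    consensus_support,
    distance_matrix,
    induced_taxon_tree,
    nj_tree,
    taxa_monophyletic,
    topology_similarity,
)

log = logging.getLogger(__name__)

DEFAULTS = {
    "k": 5,
    "reduction": 0.90,
    "subgroups": 5,
    "group_size": 20,
    "max_reps": 10,
    "convergence": 0.95,
    "replicates": 100,
    "seed": 0,
    "min_region_len": 5,
    "conserved_cutoff": 8,
}


def read_config(path: str | os.PathLike) -> dict:
    """Flat ``key = value`` config; '#' comments and blank lines ignored."""
    conf: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            conf[key] = value
    return conf


def _coerce(conf: dict) -> dict:
    out = dict(DEFAULTS)
    ints = {"k", "subgroups", "group_size", "max_reps", "replicates", "seed",
            "min_region_len", "conserved_cutoff"}
    floats = {"reduction", "convergence"}
    errors = []
    for key, value in conf.items():
        try:
            if key in ints:
                out[key] = int(value)
            elif key in floats:
                out[key] = float(value)
            else:
                out[key] = value
        except ValueError:
            errors.append(f"bad value for {key}: {value!r}")
    if "fixture" not in out and "fasta" not in out:
        errors.append("config needs either 'fixture' or 'fasta' + 'species_table'")
    if "fasta" in out and "species_table" not in out:
        errors.append("'fasta' requires 'species_table'")
    if errors:
        raise ValueError("; ".join(errors))
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: dict | str | os.PathLike, out_dir: str | os.PathLike) -> Path:
    """Run the full analysis described by *config*; returns the output dir."""
    if not isinstance(config, dict):
        config = read_config(config)
    conf = _coerce(config)
    out_dir = Path(out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=".pipeline-", dir=out_dir.parent))
    try:
        manifest = _run(conf, tmp)
        (tmp / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        if out_dir.exists():
            shutil.rmtree(out_dir)
        os.replace(tmp, out_dir)
    except Exception:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    return out_dir


def _run(conf: dict, out: Path) -> dict:
    k = conf["k"]
    seed = conf["seed"]
    log.info("pipeline start: seed=%d k=%d", seed, k)

    aln = None
    if "fixture" in conf:
        proteomes, truth = fixture(conf["fixture"])
        aln = concatenated_alignment(proteomes)
        kio.write_proteomes(proteomes, out / "proteomes.fasta")
        kio.write_species_table(species_table_for(proteomes), out / "species.tsv")
        kio.write_newick(truth.tree, out / "true_tree.nwk")
    else:
        table = kio.read_species_table(conf["species_table"])
        paths = [p for p in str(conf["fasta"]).split(",") if p]
        proteomes = kio.read_proteomes(paths, table)
        if "alignment" in conf:
            aln = kio.read_alignment(conf["alignment"])

    rows = cv_matrix(proteomes, k)
    export_cv_tsv(proteomes[0], k, out / f"cv_{proteomes[0].species_id}.tsv")

    phyla = sorted({p.phylum for p in proteomes})
    n = len(proteomes)
    group_size = min(conf["group_size"], n)
    n_sub = effective_subgroups(group_size, max(len(phyla), 1), conf["subgroups"])
    core, broad, _groups = extract_broad_keys(
        proteomes,
        K=k,
        group_size=group_size,
        n_subgroups=n_sub,
        max_reps=conf["max_reps"],
        convergence=conf["convergence"],
        reduction=conf["reduction"],
        seed=seed,
        rows=rows,
    )
    write_keyset(core, out / "keys_core.txt")
    write_keyset(broad, out / "keys_broad.txt")

    specific: list[KeySet] = []
    for ph in phyla:
        idx = [i for i, p in enumerate(proteomes) if p.phylum == ph]
        if len(idx) < 2:
            log.warning("phylum %s has <2 species; no specific keys", ph)
            continue
        ks = extract_specific_keys(
            [proteomes[i] for i in idx],
            K=k,
            broad=None,
            n_subgroups=conf["subgroups"],
            reduction=conf["reduction"],
            seed=seed + 1,
            rows=[rows[i] for i in idx],
            label=ph,
        )
        specific.append(ks)
        write_keyset(ks, out / f"keys_{ph}.txt")
    glob = global_keys(specific, broad) if specific else broad
    write_keyset(glob, out / "keys_global.txt")

    if len(specific) >= 2:
        st = sharing_table(specific)
        st.to_tsv(out / "sharing.tsv")
        (out / "sharing_summary.json").write_text(
            json.dumps(summarize_sharing(st), indent=2, sort_keys=True) + "\n"
        )

    dm_full = distance_matrix(rows)
    dm_keys = distance_matrix(rows, glob)
    kio.write_distance_matrix(dm_full, out / "distances_full.phy")
    kio.write_distance_matrix(dm_keys, out / "distances_keys.phy")

    stats: dict = {
        "n_species": n,
        "n_broad_keys": len(broad),
        "n_global_keys": len(glob),
    }
    if n >= 3:
        tree_full = nj_tree(dm_full)
        tree_keys = nj_tree(dm_keys)
        kio.write_newick(tree_full, out / "tree_full.nwk")
        plan = BootstrapPlan(n_replicates=conf["replicates"], seed=seed + 2)
        reps = bootstrap_trees(proteomes, plan, K=k, keys=glob)
        tree_keys = consensus_support(tree_keys, reps)
        kio.write_newick(tree_keys, out / "tree_keys.nwk", with_support=True)
        stats["keys_vs_full_similarity_pct"] = topology_similarity(
            tree_keys, tree_full
        )
        taxon_of = {p.species_id: p.phylum for p in proteomes}
        if len(phyla) >= 3:
            stats["phylum_monophyly"] = taxa_monophyletic(tree_keys, taxon_of)
            stats["keys_vs_full_phylum_similarity_pct"] = topology_similarity(
                induced_taxon_tree(tree_keys, taxon_of),
                induced_taxon_tree(tree_full, taxon_of),
            )

    if len(broad):
        for mode in MODES:
            composition_profile(broad, mode).to_tsv(out / f"profile_{mode}.tsv")

    if aln is not None and len(broad):
        prof = conservativity_profile(aln)
        with open(out / "conservativity.tsv", "w") as fh:
            fh.write("window_start\tscore\n")
            for start in sorted(prof.scores):
                fh.write(f"{start}\t{prof.scores[start]}\n")
        coverages = [map_keys(row, broad) for row in aln.row_strings()]
        regions = accumulation_regions(
            coverages, min_total=1, min_len=conf["min_region_len"]
        )
        regions_to_bed(regions, out / "accumulation_regions.bed")
        stats["conservation"] = overlap_summary(
            regions, prof, conserved_cutoff=conf["conserved_cutoff"]
        )

    files = sorted(p.name for p in out.iterdir() if p.is_file())
    return {
        "parameters": {key: conf[key] for key in sorted(conf)},
        "statistics": stats,
        "outputs": {name: _sha256(out / name) for name in files},
    }
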