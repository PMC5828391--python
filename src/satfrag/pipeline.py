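"""End-to-end orchestration: simulate -> merge -> map -> motifs -> enrich -> dimers.

A run is driven by a :class:`RunConfig`; every stage writes plain-text
tables into the output directory and a manifest records parameters,
package versions and input checksums, so a run is reproducible from its
manifest alone. All randomness flows from the single config seed.

Also home to :func:`simulated_enrichment_table`, the counts-level
experiment that generates a panel of arrays across a divergence
gradient and measures how well the motif-enrichment correlation
recovers the simulated box-score -> occupancy link.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dimers import classify, occupancy_fold_range, per_dimer_occupancy
from .enrichment import (
    DEFAULT_SCALE,
    calibrate,
    correlate_motif_enrichment,
    fold_enrichment,
    percent_recovery,
)
from .mapping import (
    align_end_to_end,
    build_track,
    fold_to_middle_dimer,
    triplicate_consensus,
    write_bedgraph,
)
from .merge import merge_fastq
from .motifs import motif_density, scan_motifs
from .synthetic import (
    FRACTIONS,
    DimerUnit,
    FragmentModel,
    SatelliteArray,
    ancestral_dimer,
    assign_truth_occupancy,
    default_link,
    emit_fastq,
    evolve_array,
    random_genome,
    simulate_background_fragments,
    simulate_fragments,
)

IGG = "IgG"


@dataclass
class RunConfig:
    """Every knob of a pipeline run, with simulation-scale defaults.

    ``mode`` selects merged long-read analysis (250 x 250, fragment
    lengths known) or short-read end counting (25 x 25, where merging is
    impossible and only mapped-read counts are produced).
    """

    out_dir: str = "satfrag_run"
    seed: int = 1
    mode: str = "merged_250"  # or "short_read_25"
    # simulation
    n_arrays: int = 6
    units_per_array: int = 12
    max_divergence: float = 0.15
    antibodies: tuple[str, ...] = ("CENP-A", "CENP-B")
    n_fragments: int = 3000  # per antibody, across all arrays
    n_igg_fragments: int = 3000
    spike_reads: int = 500  # mean spike-in depth per sample
    read_length: int = 250
    per_base_error: float = 0.001
    noise_sd: float = 0.7  # lognormal sd of per-unit occupancy noise
    jitter_sd: float = 40.0
    # merging
    min_quality: int = 25
    min_length: int = 25
    min_overlap: int = 15
    # mapping
    max_mismatch_frac: float = 0.1
    # enrichment
    scale_const: float = DEFAULT_SCALE
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("merged_250", "short_read_25"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "short_read_25":
            self.read_length = 25

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "antibodies" in d:
            d["antibodies"] = tuple(d["antibodies"])
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["antibodies"] = list(self.antibodies)
        return d


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_array_panel(
    n_arrays: int,
    units_per_array: int,
    max_divergence: float,
    seed: int,
    noise_sd: float = 0.7,
) -> list[SatelliteArray]:
    """Arrays spanning a divergence gradient, alternating 340/342 periods,
    with ground-truth occupancy attached."""
    divergences = np.linspace(0.0, max_divergence, n_arrays)
    seeds = _child_seeds(seed, 3 * n_arrays)
    arrays = []
    for i, div in enumerate(divergences):
        period = 340 if i % 2 == 0 else 342
        # the array's age is carried by its founder dimer; copies within
        # an array stay nearly homogeneous (young expansion)
        founder = evolve_array(
            ancestral_dimer(period=period), 1, float(div), seed=seeds[3 * i]
        ).units[0]
        arr = evolve_array(
            founder, units_per_array, min(float(div), 0.03), seed=seeds[3 * i + 1],
            name=f"array{i:02d}_p{period}",
        )
        arrays.append(
            assign_truth_occupancy(arr, default_link, noise_sd, seed=seeds[3 * i + 2])
        )
    return arrays


def consensus_unit(array: SatelliteArray) -> DimerUnit:
    """Per-position majority consensus over an array's units — the
    single-dimer reference a contig is represented by."""
    mat = np.array(
        [np.frombuffer(u.sequence.encode(), dtype=np.uint8) for u in array.units]
    )
    cons = np.empty(mat.shape[1], dtype=np.uint8)
    for j in range(mat.shape[1]):
        vals, counts = np.unique(mat[:, j], return_counts=True)
        cons[j] = vals[np.argmax(counts)]
    return DimerUnit(
        sequence=cons.tobytes().decode(),
        cenpb_box_offset=array.units[0].cenpb_box_offset,
        box_strand=array.units[0].box_strand,
    )


def _write_fasta(path: Path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def run_pipeline(config: RunConfig, resume: bool = False) -> Path:
    """Execute the full simulated workflow; returns the output directory.

    Deterministic for a fixed config. With ``resume`` the simulation
    stage is skipped when its outputs already exist.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = iter(_child_seeds(config.seed, 1000))

    # ---- stage 1: simulate ------------------------------------------------
    arrays = build_array_panel(
        config.n_arrays, config.units_per_array, config.max_divergence,
        seed=next(seeds), noise_sd=config.noise_sd,
    )
    spike_genome = random_genome(5000, seed=next(seeds))
    model = FragmentModel()

    _write_fasta(out / "arrays.fasta", [(a.name, a.sequence) for a in arrays])
    _write_fasta(out / "spike_genome.fasta", [("spike", spike_genome)])
    with open(out / "units.bed", "w") as fh:
        for a in arrays:
            for (s, e), box in zip(a.unit_intervals(), a.box_starts()):
                fh.write(f"{a.name}\t{s}\t{e}\tbox_start={box}\n")

    total_occ = np.array([a.truth_occupancy.sum() for a in arrays])
    samples: dict[tuple[str, str], dict] = {}
    fastq_done = resume and (out / "samples.tsv").exists()
    rng = np.random.default_rng(next(seeds))
    for antibody in list(config.antibodies) + [IGG]:
        by_sample: dict[str, list] = {f: [] for f in FRACTIONS}
        n_total = config.n_igg_fragments if antibody == IGG else config.n_fragments
        per_array = rng.multinomial(
            n_total,
            np.ones(len(arrays)) / len(arrays)
            if antibody == IGG
            else total_occ / total_occ.sum(),
        )
        for a, n_arr in zip(arrays, per_array):
            if n_arr == 0:
                continue
            if antibody == IGG:
                frags = simulate_background_fragments(
                    a, model, int(n_arr), seed=next(seeds),
                    id_prefix=f"{a.name}.bg",
                )
            else:
                frags = simulate_fragments(
                    a, model, int(n_arr), seed=next(seeds),
                    jitter_sd=config.jitter_sd, id_prefix=f"{a.name}.frag",
                )
            for f in frags:
                by_sample[f.fraction].append(f)
        for fraction in FRACTIONS:
            name = f"{antibody}_{fraction}"
            n_spike = int(rng.integers(config.spike_reads // 2, config.spike_reads * 2))
            paths = {
                "r1": out / f"{name}.R1.fastq",
                "r2": out / f"{name}.R2.fastq",
                "truth": out / f"{name}.truth.tsv",
            }
            if not fastq_done:
                emit_fastq(
                    by_sample[fraction], paths["r1"], paths["r2"], paths["truth"],
                    read_length=config.read_length,
                    per_base_error=config.per_base_error,
                    spike_in=(spike_genome, n_spike),
                    seed=next(seeds),
                )
            samples[(antibody, fraction)] = {**paths, "n_spike": n_spike}

    with open(out / "samples.tsv", "w") as fh:
        fh.write("sample\tantibody\tfraction\tr1\tr2\tspike_reads\n")
        for (ab, fr), info in samples.items():
            fh.write(
                f"{ab}_{fr}\t{ab}\t{fr}\t{info['r1'].name}\t{info['r2'].name}"
                f"\t{info['n_spike']}\n"
            )

    # ---- stage 2: merge ---------------------------------------------------
    merged: dict[tuple[str, str], list] = {}
    len_rows = []
    for key, info in samples.items():
        if config.mode == "short_read_25":
            # 25x25 pairs cannot overlap; use R1 sequences for end counting
            from .merge import MergedFragment, read_paired_fastq

            frags = [
                MergedFragment(id=n, sequence=s1, quality=q1, n_overlap=0,
                               source="unmerged_pair")
                for n, s1, q1, _, _ in read_paired_fastq(info["r1"], info["r2"])
            ]
        else:
            frags, _ = merge_fastq(
                info["r1"], info["r2"],
                min_quality=config.min_quality,
                min_length=config.min_length,
                min_overlap=config.min_overlap,
            )
        merged[key] = frags
        len_rows += [
            {"sample": f"{key[0]}_{key[1]}", "fragment_id": f.id, "length": f.length}
            for f in frags
        ]
    pd.DataFrame(len_rows).to_csv(out / "fragment_lengths.tsv", sep="\t", index=False)

    # ---- stage 3: map to triplicated consensi ----------------------------
    consensi = {a.name: consensus_unit(a) for a in arrays}
    refs = {name: triplicate_consensus(u) for name, u in consensi.items()}
    counts: dict[tuple[str, str], dict[str, int]] = {}
    spike_counts: dict[tuple[str, str], int] = {}
    folded: dict[tuple[str, str, str], np.ndarray] = {}
    hit_rows = []
    for key, frags in merged.items():
        per_array_hits: dict[str, list] = {n: [] for n in refs}
        n_spike = 0
        for frag in frags:
            if frag.id.startswith("spike_"):
                n_spike += 1
                continue
            best_hit, best_ref = None, None
            for ref_name, ref_seq in refs.items():
                if frag.length > len(ref_seq):
                    continue
                hit = align_end_to_end(
                    frag, ref_seq, ref_name=ref_name,
                    max_mismatch_frac=config.max_mismatch_frac,
                )
                if hit and (best_hit is None or hit.n_mismatches < best_hit.n_mismatches):
                    best_hit, best_ref = hit, ref_name
            if best_hit is not None:
                per_array_hits[best_ref].append(best_hit)
                hit_rows.append(
                    {
                        "sample": f"{key[0]}_{key[1]}",
                        "fragment_id": best_hit.fragment_id,
                        "ref": best_ref,
                        "start": best_hit.start,
                        "end": best_hit.end,
                        "strand": best_hit.strand,
                        "n_mismatches": best_hit.n_mismatches,
                    }
                )
        counts[key] = {n: len(h) for n, h in per_array_hits.items()}
        spike_counts[key] = max(n_spike, 1)
        for ref_name, hits in per_array_hits.items():
            if hits:
                period = len(consensi[ref_name])
                folded[(key[0], key[1], ref_name)] = fold_to_middle_dimer(hits, period)
    pd.DataFrame(hit_rows).to_csv(out / "hits.tsv", sep="\t", index=False)
    for (ab, fr, ref_name), prof in folded.items():
        if ab == config.antibodies[0]:
            write_bedgraph(prof, out / f"folded.{ab}_{fr}.{ref_name}.bedgraph",
                           ref_name=ref_name)

    # ---- stage 4: motifs --------------------------------------------------
    motif_rows = []
    for a in arrays:
        summ = motif_density(a.sequence, ref_name=a.name)
        motif_rows.append(
            {
                "contig": a.name,
                "best_score": summ.best_score,
                "density": summ.density,
                "n_hits": summ.n_hits,
                "mean_box_score": float(a.box_scores().mean()),
            }
        )
    motif_df = pd.DataFrame(motif_rows).set_index("contig")
    motif_df.to_csv(out / "motifs.tsv", sep="\t")
    with open(out / "motif_hits.bed", "w") as fh:
        for a in arrays:
            for h in scan_motifs(a.sequence, ref_name=a.name):
                fh.write(
                    f"{a.name}\t{h.start}\t{h.end}\tbox\t{h.score:g}\t{h.strand}\n"
                )

    # ---- stage 5: enrichment ---------------------------------------------
    enr_rows = []
    for (ab, fr), per_array in counts.items():
        if ab == IGG:
            continue
        for ref_name, raw in per_array.items():
            cal = calibrate(raw, spike_counts[(ab, fr)], config.scale_const)
            igg_cal = calibrate(
                counts[(IGG, fr)][ref_name], spike_counts[(IGG, fr)],
                config.scale_const,
            )
            enr_rows.append(
                {
                    "contig": ref_name,
                    "antibody": ab,
                    "fraction": fr,
                    "raw_count": raw,
                    "calibrated": cal,
                    "fold_enrichment": fold_enrichment(cal, igg_cal, config.pseudocount),
                    "best_score": motif_df.loc[ref_name, "best_score"],
                    "density": motif_df.loc[ref_name, "density"],
                }
            )
    enr = pd.DataFrame(enr_rows)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    rec_rows = []
    for ab in list(config.antibodies) + [IGG]:
        frac_cal = {
            fr: calibrate(sum(counts[(ab, fr)].values()), spike_counts[(ab, fr)],
                          config.scale_const)
            for fr in FRACTIONS
        }
        if sum(frac_cal.values()) > 0:
            rec = percent_recovery(frac_cal)
            for fr, pct in rec.items():
                rec_rows.append({"antibody": ab, "fraction": fr, "percent": pct})
    pd.DataFrame(rec_rows).to_csv(out / "recovery.tsv", sep="\t", index=False)

    corr_rows = []
    for ab in config.antibodies:
        for x in ("best_score", "density"):
            for fr in list(FRACTIONS) + ["pooled"]:
                sub = enr[enr.antibody == ab]
                if fr != "pooled":
                    sub = sub[sub.fraction == fr]
                else:
                    sub = sub.groupby("contig", as_index=False).agg(
                        {"fold_enrichment": "mean", x: "first"}
                    )
                try:
                    r, n = correlate_motif_enrichment(sub, x=x)
                except ValueError:
                    continue
                corr_rows.append(
                    {"antibody": ab, "x": x, "fraction": fr, "pearson_r": r, "n": n}
                )
    pd.DataFrame(corr_rows).to_csv(out / "correlations.tsv", sep="\t", index=False)

    # ---- stage 6: dimer structure ----------------------------------------
    dimer_rows = []
    ab0 = config.antibodies[0]
    for a in arrays:
        pooled = []
        for fr in FRACTIONS:
            pooled += [
                f for f in merged[(ab0, fr)]
                if f.id.startswith(a.name + ".") and f.length <= len(a)
            ]
        hits = []
        for frag in pooled:
            hit = align_end_to_end(
                frag, a.sequence, ref_name=a.name,
                max_mismatch_frac=config.max_mismatch_frac,
            )
            if hit:
                hits.append(hit)
        if len(hits) < 2:
            continue
        track = build_track(hits, a.sequence, ref_name=a.name)
        profiles = [
            classify(p)
            for p in per_dimer_occupancy(track, a.unit_intervals(), a.box_starts())
        ]
        try:
            fold_range = occupancy_fold_range(profiles, config.pseudocount)
        except ValueError:
            fold_range = float("nan")
        for p in profiles:
            dimer_rows.append(
                {
                    "contig": a.name,
                    "unit_index": p.unit_index,
                    "occupancy": p.occupancy,
                    "monomer_a_occ": p.monomer_a_occ,
                    "monomer_b_occ": p.monomer_b_occ,
                    "centroid_offset": p.centroid_offset,
                    "orientation": p.orientation,
                    "symmetry": p.symmetry,
                    "array_fold_range": fold_range,
                    "truth_occupancy": float(a.truth_occupancy[p.unit_index]),
                }
            )
    pd.DataFrame(dimer_rows).to_csv(out / "dimer_profiles.tsv", sep="\t", index=False)

    # ---- manifest ---------------------------------------------------------
    manifest = {
        "satfrag_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config.to_dict(),
        "inputs": {
            str(info["r1"].name): _sha256(info["r1"]) for info in samples.values()
        },
        "stages": ["simulate", "merge", "map", "motifs", "enrich", "dimers"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def make_fixtures(seed: int = 1, out_dir: str | Path = "fixtures") -> Path:
    """Small complete dataset (2 arrays, CENP-A + CENP-B + IgG across the
    four salt fractions) used by the test suite and the README walkthrough."""
    config = RunConfig(
        out_dir=str(out_dir),
        seed=seed,
        n_arrays=2,
        units_per_array=8,
        max_divergence=0.08,
        n_fragments=1500,
        n_igg_fragments=1500,
        spike_reads=300,
    )
    return run_pipeline(config)


def simulated_enrichment_table(
    n_arrays: int = 40,
    units_per_array: int = 4,
    max_divergence: float = 0.2,
    noise_sd: float = 0.7,
    depth: float = 50.0,
    igg_depth: float = 50.0,
    pseudocount: float = 1.0,
    seed: int = 1,
) -> pd.DataFrame:
    """Counts-level divergence-panel experiment for correlation recovery.

    Generates ``n_arrays`` small arrays whose *founder* dimers carry
    divergence uniform on [0, max_divergence] — emulating contigs of
    different evolutionary age, each represented by its consensus dimer —
    expanded into nearly homogeneous copies (2% within-array divergence).
    Occupancy follows the default box-score link with lognormal noise;
    antibody counts are Poisson proportional to total array occupancy,
    IgG counts flat. Returns one row per array with motif statistics and
    fold enrichment — the input shape expected by
    :func:`satfrag.enrichment.correlate_motif_enrichment`.
    """
    rng = np.random.default_rng(seed)
    seeds = _child_seeds(int(rng.integers(2**31 - 1)), 3 * n_arrays)
    rows = []
    for i in range(n_arrays):
        div = float(rng.uniform(0.0, max_divergence))
        founder = evolve_array(
            ancestral_dimer(period=340), 1, div, seed=seeds[3 * i]
        ).units[0]
        arr = evolve_array(founder, units_per_array, 0.02, seed=seeds[3 * i + 1],
                           name=f"panel{i:03d}")
        arr = assign_truth_occupancy(arr, default_link, noise_sd, seed=seeds[3 * i + 2])
        target = rng.poisson(depth * arr.truth_occupancy.sum() / units_per_array)
        igg = rng.poisson(igg_depth)
        summ = motif_density(arr.sequence, ref_name=arr.name)
        rows.append(
            {
                "contig": arr.name,
                "divergence": div,
                "best_score": summ.best_score,
                "density": summ.density,
                "mean_box_score": float(arr.box_scores().mean()),
                "fold_enrichment": fold_enrichment(float(target), float(igg),
                                                   pseudocount),
            }
        )
    return pd.DataFrame(rows)
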