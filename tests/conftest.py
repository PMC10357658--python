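import os

import pytest

from editome import pipeline
from editome.model import ConsensusSite, SampleEvidence, SiteKey
from editome.simulate import SimConfig


def make_site(
    pos,
    methods,
    n_samples=2,
    level=0.5,
    context=None,
    chrom="chr1",
    strand="+",
    annotated=None,
):
    """Build a ConsensusSite with uniform per-sample evidence for rule tests."""
    methods = frozenset(methods)
    per_sample = {
        f"S{i + 1:02d}": SampleEvidence(methods=methods, level=level)
        for i in range(n_samples)
    }
    return ConsensusSite(
        key=SiteKey(chrom, pos, strand),
        per_sample=per_sample,
        annotated=annotated,
        context=context,
    )


def small_sim_config(seed=0, **overrides):
    """A scaled-down generator configuration for fast structural tests."""
    from editome.model import RED_ML, REDITOOLS, SPRINT

    defaults = dict(
        rng_seed=seed,
        genome_length=400_000,
        n_contigs=2,
        n_genes=20,
        coding_fraction=0.6,
        repeat_fraction=0.25,
        n_vlincs=4,
        n_samples=4,
        n_true_sites=80,
        singleton_fp_per_sample={REDITOOLS: 40, RED_ML: 6, SPRINT: 6},
        recurrent_fp_count=6,
        hidden_snp_count=4,
        known_snp_count=8,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def sim_workspace(tmp_path_factory):
    """Default-seed synthetic fixture plus one full pipeline run, shared by
    all end-to-end tests."""
    root = tmp_path_factory.mktemp("sim")
    fixture_dir = root / "fixture"
    run_dir = root / "run"
    sim = pipeline.simulate_fixture(SimConfig(), str(fixture_dir))
    manifest = pipeline.run_full_pipeline(str(fixture_dir), str(run_dir))
    return {
        "sim": sim,
        "fixture_dir": str(fixture_dir),
        "run_dir": str(run_dir),
        "manifest": manifest,
    }


# --- a small deterministic annotation bundle used by io/annotation tests ---

TOY_CONTIG = "chrT"
TOY_LENGTH = 1000


def write_toy_bundle(directory):
    """Tiny hand-checkable bundle on one 1 kb contig.

    Layout (0-based half-open):
      tx1 '+', protein-coding: exons (100,200)+(300,400), CDS (150,200)+(300,350)
        -> UTR5 (100,150), intron (200,300), UTR3 (350,400)
      tx2 '-', lncRNA: exons (500,560)+(640,700), intron (560,640)
      vlinc1 '+': (150, 450); repeats AluY (800,850) and L1 (860,880)
    Sequence repeats 'ACGT', so the base at 0-based i is 'ACGT'[i % 4].
    """
    os.makedirs(directory, exist_ok=True)
    seq = ("ACGT" * (TOY_LENGTH // 4 + 1))[:TOY_LENGTH]
    with open(os.path.join(directory, "genome.fa"), "w") as fh:
        fh.write(f">{TOY_CONTIG}\n")
        for i in range(0, TOY_LENGTH, 60):
            fh.write(seq[i : i + 60] + "\n")
    with open(os.path.join(directory, "genes.gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"{TOY_CONTIG}\t.\tgene\t101\t400\t.\t+\t.\tID=g1\n")
        fh.write(
            f"{TOY_CONTIG}\t.\tmRNA\t101\t400\t.\t+\t.\t"
            "ID=tx1;Parent=g1;biotype=protein_coding\n"
        )
        fh.write(f"{TOY_CONTIG}\t.\texon\t101\t200\t.\t+\t.\tID=tx1.e1;Parent=tx1\n")
        fh.write(f"{TOY_CONTIG}\t.\texon\t301\t400\t.\t+\t.\tID=tx1.e2;Parent=tx1\n")
        fh.write(f"{TOY_CONTIG}\t.\tCDS\t151\t200\t.\t+\t0\tID=tx1.c1;Parent=tx1\n")
        fh.write(f"{TOY_CONTIG}\t.\tCDS\t301\t350\t.\t+\t0\tID=tx1.c2;Parent=tx1\n")
        fh.write(f"{TOY_CONTIG}\t.\tgene\t501\t700\t.\t-\t.\tID=g2\n")
        fh.write(
            f"{TOY_CONTIG}\t.\tlnc_RNA\t501\t700\t.\t-\t.\t"
            "ID=tx2;Parent=g2;biotype=lncRNA\n"
        )
        fh.write(f"{TOY_CONTIG}\t.\texon\t501\t560\t.\t-\t.\tID=tx2.e1;Parent=tx2\n")
        fh.write(f"{TOY_CONTIG}\t.\texon\t641\t700\t.\t-\t.\tID=tx2.e2;Parent=tx2\n")
    with open(os.path.join(directory, "repeats.bed"), "w") as fh:
        fh.write(f"{TOY_CONTIG}\t800\t850\tAluY\n")
        fh.write(f"{TOY_CONTIG}\t860\t880\tL1\n")
    with open(os.path.join(directory, "vlincs.bed"), "w") as fh:
        fh.write(f"{TOY_CONTIG}\t150\t450\tvlinc1\t0\t+\n")
    with open(os.path.join(directory, "variants.tsv"), "w") as fh:
        fh.write("chrom\tpos\n")
        fh.write(f"{TOY_CONTIG}\t11\n")
    with open(os.path.join(directory, "map100.bedgraph"), "w") as fh:
        fh.write(f"{TOY_CONTIG}\t0\t{TOY_LENGTH}\t1\n")
    with open(os.path.join(directory, "map24.bedgraph"), "w") as fh:
        fh.write(f"{TOY_CONTIG}\t0\t{TOY_LENGTH}\t0.9\n")
    with open(os.path.join(directory, "db_sites.tsv"), "w") as fh:
        fh.write("chrom\tpos\tstrand\n")
        fh.write(f"{TOY_CONTIG}\t101\t+\n")
        fh.write(f"{TOY_CONTIG}\t102\t.\n")
    return directory


@pytest.fixture(scope="session")
def toy_bundle_dir(tmp_path_factory):
    return write_toy_bundle(str(tmp_path_factory.mktemp("toy")))


@pytest.fixture(scope="session")
def toy_bundle(toy_bundle_dir):
    from editome import io

    return io.read_bundle_dir(toy_bundle_dir)
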