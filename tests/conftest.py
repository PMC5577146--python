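import numpy as np
import pytest
from pyfaidx import Fasta

from tailsweep.annotation import read_annotation
from tailsweep.core import GenotypeMatrix, SampleGroups, VariantSite
from tailsweep.io import read_cohort
from tailsweep.simulate import SimConfig, write_fixture

BED_CLASSES = ("CpG", "regulatory", "repeat", "CNE", "gap", "lowMQ")


def bed_map(fixture_dir):
    return {cls: str(fixture_dir / f"{cls.lower()}.bed") for cls in BED_CLASSES}


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The default synthetic cohort (10 NT / 5 ST / 7 LT + 2 outgroup), seed 0."""
    outdir = tmp_path_factory.mktemp("fixture")
    return write_fixture(SimConfig(seed=0), outdir)


@pytest.fixture(scope="session")
def cohort(fixture_bundle):
    gm, groups = read_cohort(fixture_bundle.vcf, fixture_bundle.groups)
    return gm, groups


@pytest.fixture(scope="session")
def annotation(fixture_bundle):
    return read_annotation(bed_map(fixture_bundle.outdir), fixture_bundle.gff)


@pytest.fixture(scope="session")
def reference(fixture_bundle):
    return Fasta(str(fixture_bundle.fasta))


def make_gm(codes, chrom="chr1", start_pos=100, samples=None, ref="A", alt="G"):
    """GenotypeMatrix from a (n_sites, n_samples) list of genotype codes."""
    codes = np.asarray(codes, dtype=np.int8)
    if samples is None:
        samples = [f"s{i}" for i in range(codes.shape[1])]
    sites = [VariantSite(chrom, start_pos + i, ref, alt) for i in range(codes.shape[0])]
    return GenotypeMatrix(sites, list(samples), codes)


def make_groups(samples, labels):
    return SampleGroups(dict(zip(samples, labels)))
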