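import numpy as np
import pytest

from acmgml.engine import EngineConfig
from acmgml.io_annotation import AnnotatedVariant, VariantKey
from acmgml.synthetic import (SyntheticConfig, generate_fixture_bank,
                              simulate_dataset)

CONSEQUENCE_POOL = ("missense", "synonymous", "stop_gained", "stop_lost",
                    "frameshift", "inframe_insertion", "inframe_deletion",
                    "splice_acceptor", "splice_donor", "other")

_AA = "ARNDCQEGHILKMFPSTWYV"


def random_variant(rng: np.random.Generator, pos_base: int = 41_200_000) -> AnnotatedVariant:
    """Fuzzer: a random but schema-valid annotated variant."""
    chrom = ("17", "13")[rng.integers(2)]
    bases = "ACGT"
    ref = bases[rng.integers(4)]
    alt = bases[(bases.index(ref) + rng.integers(1, 4)) % 4]
    key = VariantKey.make(chrom, pos_base + int(rng.integers(0, 10_000_000)), ref, alt)
    fields: dict = {"consequence": CONSEQUENCE_POOL[rng.integers(len(CONSEQUENCE_POOL))]}

    def maybe(p=0.5):
        return rng.random() < p

    if maybe():
        fields["af_gnomad_noncancer"] = float(rng.uniform(0, 0.2)) if maybe(0.8) else 0.0
    if maybe():
        fields["af_exac_nontcga"] = float(rng.uniform(0, 0.2))
    if maybe(0.3):
        an_case, an_control = 1000, 100000
        fields.update(ac_case=int(rng.integers(0, 20)), an_case=an_case,
                      ac_control=int(rng.integers(0, 50)), an_control=an_control)
    if maybe():
        fields["gerp_rs"] = float(rng.uniform(-5, 6))
    if maybe(0.4):
        fields["ada_score"] = float(rng.uniform(0, 1))
        fields["rf_score"] = float(rng.uniform(0, 1))
    if maybe(0.4):
        fields["metasvm_pred"] = ("deleterious", "tolerated")[rng.integers(2)]
    if maybe(0.4):
        fields["condel_pred"] = ("deleterious", "neutral")[rng.integers(2)]
    if maybe(0.4):
        fields["mmsplice_pathogenicity"] = float(rng.uniform(0, 1))
    if maybe(0.5):
        fields["protein_position"] = int(rng.integers(1, 3400))
        if fields["consequence"] == "missense" and maybe(0.8):
            aa_ref = _AA[rng.integers(20)]
            fields["aa_ref"] = aa_ref
            fields["aa_alt"] = _AA[(_AA.index(aa_ref) + rng.integers(1, 20)) % 20]
    if maybe(0.5):
        fields["exon_index"] = int(rng.integers(1, 28))
        fields["exon_total"] = int(rng.integers(fields["exon_index"], 28))
    fields["in_repeat_region"] = bool(maybe(0.2))
    v = AnnotatedVariant(key=key, **fields)
    v.validate()
    return v


@pytest.fixture(scope="session")
def fixture_bank():
    return generate_fixture_bank(EngineConfig())


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """Noise-free synthetic dataset (n=300) plus its on-disk file set."""
    outdir = tmp_path_factory.mktemp("sim")
    paths, dataset = simulate_dataset(
        SyntheticConfig(n_variants=300, seed=11), outdir)
    return paths, dataset
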