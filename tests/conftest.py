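import numpy as np
import pytest

import retrocopy as rc
from retrocopy.models import GeneModel, Mate, AlignedPair


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full simulate->detect->map->annotate run shared by the suite."""
    out = tmp_path_factory.mktemp("e2e")
    return rc.run_end_to_end(rc.SimConfig(seed=1), out)


@pytest.fixture(scope="session")
def sim_result(pipeline_result):
    return pipeline_result.sim


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def parse_cigar(text: str) -> list[tuple[str, int]]:
    ops, num = [], ""
    for ch in text:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops


def mk_mate(chrom="chr1", pos=0, cigar="75M", strand="+", mapq=60, seq=None):
    ops = parse_cigar(cigar)
    qlen = sum(n for op, n in ops if op in "MIS=X")
    return Mate(chrom=chrom, pos=pos, strand=strand, cigar_ops=ops,
                mapq=mapq, seq=seq if seq is not None else "A" * qlen)


def mk_pair(m1, m2, name="r", sample="tumour"):
    return AlignedPair(read_name=name, sample=sample, mate1=m1, mate2=m2)


def mk_gene(exons, strand="+", chrom="chr1", gene_id="G1", cds=None,
            biotype="protein_coding"):
    cds_start, cds_end = cds if cds else (None, None)
    return GeneModel(gene_id=gene_id, gene_name=gene_id,
                     transcript_id="T" + gene_id, chrom=chrom, strand=strand,
                     exons=tuple(exons), cds_start=cds_start, cds_end=cds_end,
                     biotype=biotype)
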