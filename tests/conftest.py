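import numpy as np
import pytest

from telandscape.classification import parse_classification_label
from telandscape.repeatio import RepeatRecord

OUT_HEADER = (
    "   SW  perc perc perc  query     position in query    matching"
    "          repeat             position in repeat\n"
    "score  div. del. ins.  sequence  begin end   (left)   repeat"
    "            class/family     begin  end    (left)  ID\n"
    "\n"
)

OUT_BODY = (
    "  500   3.2  0.0  0.0  read1  1 150 (100) + Gypsy-7  LTR/Gypsy  1 150 (0)  1\n"
    "  300  12.5  0.0  0.0  read1  100 200 (50) C L1-3  LINE/L1  1 101 (0)  2 *\n"
    "  410   1.1  0.0  0.0  read2  20 240 (10) + Jockey-1  LINE/Jockey  1 221 (0)  3\n"
    "  120  28.4  0.0  0.0  read3  5 90 (160) + Unk-22  Unknown  1 86 (0)  4\n"
)


@pytest.fixture
def out_text() -> str:
    return OUT_HEADER + OUT_BODY


def make_record(
    query_id="r1",
    query_len=250,
    start=0,
    end=100,
    label="LINE/Jockey",
    pct_div=1.0,
    score=100.0,
    consensus_id="cons",
    strand="+",
    overlap_flag=False,
) -> RepeatRecord:
    return RepeatRecord(
        query_id=query_id,
        query_len=query_len,
        start=start,
        end=end,
        consensus_id=consensus_id,
        classification=parse_classification_label(label),
        pct_div=pct_div,
        score=score,
        strand=strand,
        overlap_flag=overlap_flag,
    )


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate_dna(seq: str, n_sub: int, rng: np.random.Generator) -> str:
    out = list(seq)
    rot = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for i in rng.choice(len(seq), size=n_sub, replace=False):
        out[i] = rot[out[i]]
    return "".join(out)
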