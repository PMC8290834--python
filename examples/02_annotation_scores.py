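"""Annotation confidence scoring from multi-method evidence.

Scores one well-supported gene (identical ortholog names, reliable
structure, two agreeing EC predictions) and one weakly supported gene,
then bins them into basic/medium/high confidence. The 0-9 final score is
the plain sum of the three evidence components.
"""

from minigem.annotation import EvidenceRecord, StructureMetrics, final_score

strong = EvidenceRecord(
    gene="mfl468",
    name="eno",
    ortholog_names={"M. genitalium": "eno", "M. pneumoniae": "eno"},
    ec_by_method={"DETECT": "4.2.1.11", "RefSeq": "4.2.1.11"},
    detect_probability=0.99,
    structure=StructureMetrics(
        e_value=1e-20,
        domain_identity=0.55,
        domain_similarity=0.75,
        is_transmembrane=False,
        c_score=1.4,
        tm_score=0.92,
    ),
)
weak = EvidenceRecord(
    gene="mfl999",
    name="yabQ",
    ortholog_names={"M. genitalium": "ymfJ"},
    ec_by_method={"COFACTOR": "3.6.1.1"},
)

for record in (strong, weak):
    s = final_score(record)
    print(
        f"{s.gene}: proteome={s.proteome_score} structure={s.structure_score} "
        f"ec={s.ec_score} -> final={s.final_score} ({s.bin} confidence)"
        + ("  [gold-standard EC]" if s.gold_standard else "")
    )
# A score >= 7 means at least two independent evidence lines agree fully.
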