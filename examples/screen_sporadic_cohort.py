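"""Screen a candidate variant in a sporadic-case cohort and a population catalogue.

A family-private pathogenic allele should be absent from unrelated
sporadic cases and from population frequency resources.  This example
builds a 248-sample all-reference cohort (the screening logic applied to
Sanger-style per-patient validation) and looks the variant up in a small
population table.
"""

import numpy as np

from famprio import (
    ABSENT,
    GenotypeMatrix,
    population_lookup,
    screen_cohort,
)
from famprio.reference_study import CAUSAL_VARIANT

vid = CAUSAL_VARIANT.vid
samples = [f"SP{i:04d}" for i in range(248)]
cohort = GenotypeMatrix([vid], samples, np.zeros((1, 248), dtype=np.int8))

report = screen_cohort(vid, cohort)
print(f"cohort screen of {vid}:")
print(f"  samples      : {report.n_samples}")
print(f"  carriers     : {report.n_carriers}")
print(f"  allele freq  : {report.allele_freq}")
print(f"  absent       : {report.absent}")

# population catalogue holding only a common control variant
catalogue = {"12:12630669:C:T": 0.013}
for query in (vid, "12:12630669:C:T"):
    hit = population_lookup(query, catalogue)
    rendered = "ABSENT" if hit is ABSENT else f"AF={hit}"
    print(f"catalogue lookup {query}: {rendered}")
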