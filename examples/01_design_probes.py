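"""Design encoding probes for a small synthetic gene panel.

Each probe carries a 28-nt mRNA-complementary targeting region, four
18-nt readout sites (two per side) and two 20-nt PCR primer flanks.
Targeting regions with >= 17 nt of exact homology to the decoy
background are removed; each gene keeps 17-32 non-overlapping probes.
"""

import fishcoder as fc

cfg = fc.DesignConfig(rng_seed=0)
transcripts = fc.synthetic_transcripts([f"TF{i:02d}" for i in range(6)], length=1500, rng_seed=0)
decoys = fc.synthetic_transcripts([f"decoy{i}" for i in range(4)], length=1500, rng_seed=1)
# give one decoy a 300-nt stretch borrowed from TF00, the situation the
# off-target screen exists for (a paralog / repeat region)
decoys[0] = fc.TranscriptRecord(
    "decoy0", decoys[0].sequence[:600] + transcripts[0].sequence[400:700] + decoys[0].sequence[900:]
)

designs = fc.design_probe_library(transcripts, decoys, cfg)

for d in designs:
    print(
        f"{d.gene_id}: {d.n_candidate_sites} candidate sites -> "
        f"{d.n_surviving_sites} after off-target screen -> "
        f"{len(d.probes)} probes selected"
        + ("  [below 17-probe minimum]" if d.below_minimum else "")
    )

p = designs[0].probes[0]
print(f"\nexample probe for {p.gene_id} (targeting site at nt {p.site.start}):")
print(f"  full oligo ({len(p.full_sequence)} nt): {p.full_sequence}")
print(f"  targeting region reverse-complements the transcript window: "
      f"{fc.revcomp(p.targeting_region) == p.site.target_seq}")
# The counts above show the screen's attrition: sites lost between the
# two arrows shared a 17-mer with a decoy on either strand.
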