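"""Classify the coding consequence of a 13 bp deletion.

The engineered CDS pair mimics the candidate gene: a 1200 bp coding
sequence whose mutant allele lacks bases 502-514.  Because 13 is not a
multiple of 3, the downstream frame shifts and a premature stop truncates
the 399-residue protein to 173 residues, deleting the C-terminal
2OG-FeII_Oxy catalytic domain while the N-terminal DIOX_N domain survives.
"""

from bsamap import classify_effect, make_cds_fixture, translate_cds

ref, mutant, domains = make_cds_fixture(
    total_length=1200, deletion_start=502, deletion_length=13,
    target_truncated_aa=173, seed=0,
)
effect = classify_effect(ref, mutant, 502, 514, domains)

print(f"reference CDS: {len(ref)} bp -> protein {effect.protein_length_ref} aa")
print(f"deletion 502-514: {effect.deleted_length} bp removed "
      f"({effect.deleted_length} mod 3 = {effect.deleted_length % 3} -> "
      f"{'frameshift' if effect.frameshift else 'in-frame'})")
print(f"mutant protein: {effect.protein_length_mut} aa "
      f"(premature stop at CDS position {effect.stop_codon_position})")
for dom in domains:
    lost = next((d for d in effect.lost_domains if d.name == dom.name), None)
    status = "LOST (partial)" if lost and lost.partial else ("LOST" if lost else "retained")
    print(f"  domain {dom.name} ({dom.start_aa}-{dom.end_aa} aa): {status}")
print(f"\nfirst 30 residues of each protein:\n  ref {translate_cds(ref)[:30]}...\n"
      f"  mut {translate_cds(mutant)[:30]}...")
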