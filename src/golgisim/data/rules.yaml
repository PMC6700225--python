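# Enzyme specificity/action table for the mammalian Golgi N-glycosylation
# pathway. Rules are data, not code: predicates and actions are interpreted
# by golgisim.rules, so pathway variants are config edits.
#
# Two rule forms:
#   clauses: ordered list of {when, do}; the first clause whose predicate
#            holds defines the action. Multiplicity is 1.
#   site:    acts on any antenna slot currently in state `from`, converting
#            it to `to`. Multiplicity = number of eligible slots; the acted
#            slot is chosen uniformly at random.
#
# Predicate fields: glc, man, fuc (ints), armA/armB/arm4/arm6 (antenna
# states: absent|GlcNAc|Gal|Sia). Scalar = equality; {min,max} = range;
# {not: X} = inequality.
#
# Notes:
# - ManI also removes the residual glucose of GlcMan9GlcNAc2 (no separate
#   glucosidase is modelled); glucose is trimmed before any mannose.
# - Mannose trimming is one residue per event (Man9 -> ... -> Man5).
# - Fut8 requires the Mgat1 antenna in its ungalactosylated GlcNAc form,
#   so core fucosylation can precede Mgat2 but not follow galactosylation
#   of the alpha-1,3 arm.
# - No bisecting GlcNAc (Mgat3) in this enzyme set.
enzymes: [ManI, Mgat1, ManII, Mgat2, Fut8, Mgat4, Mgat5, GalT, SiaT]
rules:
  - enzyme: ManI
    clauses:
      - when: {glc: 1}
        do: {set: {glc: 0}}
      - when: {glc: 0, man: {min: 6, max: 9}, armA: absent}
        do: {inc: {man: -1}}
  - enzyme: Mgat1
    clauses:
      - when: {glc: 0, man: 5, armA: absent}
        do: {set: {armA: GlcNAc}}
  - enzyme: ManII
    clauses:
      - when: {armA: GlcNAc, man: {min: 4, max: 5}, armB: absent}
        do: {inc: {man: -1}}
  - enzyme: Mgat2
    clauses:
      - when: {man: 3, armA: {not: absent}, armB: absent}
        do: {set: {armB: GlcNAc}}
  - enzyme: Fut8
    clauses:
      - when: {fuc: 0, armA: GlcNAc}
        do: {set: {fuc: 1}}
  - enzyme: Mgat4
    clauses:
      - when: {man: 3, armA: GlcNAc, armB: {not: absent}, arm4: absent}
        do: {set: {arm4: GlcNAc}}
  - enzyme: Mgat5
    clauses:
      - when: {man: 3, armB: GlcNAc, arm6: absent}
        do: {set: {arm6: GlcNAc}}
  - enzyme: GalT
    site: {from: GlcNAc, to: Gal}
  - enzyme: SiaT
    site: {from: Gal, to: Sia}
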