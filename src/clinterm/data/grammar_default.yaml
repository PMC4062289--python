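# Default six-level noun-phrase cascade.
#
# Rules apply level by level, leftmost-longest, ties broken by file order.
# `agree` lists unification variables positionally over (case, gender,
# number); items sharing a variable must carry compatible values.  `head`
# is the 1-based rhs position whose morphology the rewritten item inherits.
#
# Level I: word classes -> basic categories.  Stop-lemma rules (NZ/AZ) come
# first so that time/introductory words never open a nominal.
- {level: 1, lhs: NZ, name: stop-noun,
   rhs: [{pos: subst, stoplist: nz}]}
- {level: 1, lhs: AZ, name: stop-modifier,
   rhs: [{pos: [adj, ppas, adv, other, conj], stoplist: az}]}
- {level: 1, lhs: N, name: nominal,
   rhs: [{pos: [subst, ger]}]}
- {level: 1, lhs: NC, name: foreign-run,
   rhs: [{pos: [foreign_subst, foreign]},
         {pos: foreign, optional: true},
         {pos: foreign, optional: true}]}
- {level: 1, lhs: NC, name: abbrev-nominal-npun,
   rhs: [{pos: ["brev:npun:nw", "brev:npun:nphr"]}]}
- {level: 1, lhs: NC, name: abbrev-nominal-pun,
   rhs: [{pos: ["brev:pun:nw", "brev:pun:nphr"]},
         {cat: interp, surface: ".", optional: true}]}
- {level: 1, lhs: AJ, name: basic-adjective, head: 2,
   rhs: [{pos: adv, optional: true},
         {pos: [adj, ppas]}]}
- {level: 1, lhs: AC, name: abbrev-adjective-npun,
   rhs: [{pos: "brev:adjw:npun"}]}
- {level: 1, lhs: AC, name: abbrev-adjective-pun,
   rhs: [{pos: "brev:adjw:pun"},
         {cat: interp, surface: ".", optional: true}]}
- {level: 1, lhs: CN, name: coord-conjunction,
   rhs: [{pos: conj, lemma: i}]}

# Level II: adverb attachment, hyphenated compound adjectives, simple
# noun-adjective agreement pairs.
- {level: 2, lhs: A, name: adjective-trailing-adverb,
   rhs: [{cat: AJ}, {pos: adv, optional: true}]}
- {level: 2, lhs: A, name: hyphen-compound-ac, head: 3,
   rhs: [{cat: AC}, {cat: interp, surface: "-"}, {cat: AJ}]}
- {level: 2, lhs: A, name: hyphen-compound-adja, head: 3,
   rhs: [{pos: adja}, {cat: interp, surface: "-"}, {cat: AJ}]}
- {level: 2, lhs: AC, name: hyphen-compound-noninflecting,
   rhs: [{cat: AC}, {cat: interp, surface: "-"}, {cat: AC}]}
- {level: 2, lhs: N, name: noun-postmodifier,
   rhs: [{cat: N, agree: [C, G, N]}, {cat: AJ, agree: [C, G, N]}]}
- {level: 2, lhs: N, name: noun-premodifier, head: 2,
   rhs: [{cat: AJ, agree: [C, G, N]}, {cat: N, agree: [C, G, N]}]}

# Level III: compound adjectival phrases, optionally coordinated with "i".
- {level: 3, lhs: ADJP, name: adjp-coordinated, head: 6,
   rhs: [{cat: A, optional: true, agree: [C, G, N]},
         {cat: A, optional: true, agree: [C, G, N]},
         {cat: A, optional: true, agree: [C, G, N]},
         {cat: A, optional: true, agree: [C, G, N]},
         {cat: CN},
         {cat: A, agree: [C, G, N]}]}
- {level: 3, lhs: ADJP, name: adjp-sequence, head: 4,
   rhs: [{cat: A, optional: true, agree: [C, G, N]},
         {cat: A, optional: true, agree: [C, G, N]},
         {cat: A, optional: true, agree: [C, G, N]},
         {cat: A, agree: [C, G, N]},
         {cat: AC, optional: true}]}

# Level IV: basic noun phrases.
- {level: 4, lhs: NB, name: nb-acronym-adjp, head: 2,
   rhs: [{cat: NC}, {cat: ADJP}]}
- {level: 4, lhs: NB, name: nb-abbrevadj-noun, head: 2,
   rhs: [{cat: AC}, {cat: N}]}
- {level: 4, lhs: NB, name: nb-noun-abbrevadj,
   rhs: [{cat: N}, {cat: AC}]}
- {level: 4, lhs: NB, name: nb-adjp-acronym,
   rhs: [{cat: ADJP}, {cat: NC}]}
- {level: 4, lhs: NB, name: nb-core, head: 2,
   rhs: [{cat: ADJP, optional: true, agree: [C, G, N]},
         {cat: N, agree: [C, G, N]},
         {cat: ADJP, optional: true, agree: [C, G, N]}]}

# Level V: genitive chains.
- {level: 5, lhs: NG, name: genitive-chain,
   rhs: [{cat: NB, case: gen, optional: true},
         {cat: NB, case: gen, optional: true},
         {cat: NB, case: gen, optional: true},
         {cat: NB, case: gen, optional: true},
         {cat: CN, optional: true},
         {cat: NB, case: gen}]}
- {level: 5, lhs: NG, name: single-group,
   rhs: [{cat: NB}]}

# Level VI: full noun phrases.
- {level: 6, lhs: X, name: phrase,
   rhs: [{cat: NG, agree: [C, G, N]},
         {cat: NG, case: gen, optional: true},
         {cat: ADJP, optional: true, agree: [C, G, N]}]}
- {level: 6, lhs: X, name: acronym-headed,
   rhs: [{cat: NC},
         {cat: NG, case: gen, optional: true},
         {cat: ADJP, optional: true}]}
- {level: 6, lhs: X, name: trailing-acronym, flag: trailing_acronym,
   rhs: [{cat: NG}, {cat: NC}]}
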