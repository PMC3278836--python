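# triplescan

Graph-theoretical detection of **multiply hydrogen-bonded RNA base
triples** — three nucleobases mutually joined so that *each* base makes at
least two base–base hydrogen bonds — in 3D coordinate files. Such triples
are unusually stable tertiary interactions (helix packing, inter-domain
staples, junction clamps in ribosomal RNA) and are the survey target of
this tool.

The tool is aimed at structural bioinformaticians who want to inventory,
classify and compare these interactions across RNA crystal structures
without manual inspection.

## Method

1. **Reduced representation.** Each base is collapsed to two pseudo-atom
   vectors (four labelled nodes). Vector X runs from the glycosidic
   nitrogen S(x) (N9 in purines, N1 in pyrimidines) through the ring
   centroid to E(x); vector Y spans the base plane perpendicular to X
   (half-length 2 Å). Both midpoints coincide at the ring centroid, so the
   two vectors of one base are always within the 1 Å intra-base midpoint
   bound that the matcher enforces.
2. **Pattern matrices.** A query triple is encoded as the matrix of
   node-pair distances between its six vector units, stored as integers in
   tenths of an ångström (10 Å → `100`), with an SS/SE/ES/EE block per
   unit pair. Patterns can be measured from any observed occurrence
   (`pattern_from_occurrence`, `triplescan build-pattern`).
3. **Ullmann subgraph isomorphism.** Patterns are matched against the
   structure's pseudo-atom graph under a distance tolerance — absolute
   (e.g. `1.7A`) or percent of the pattern distance (`60%` and above gives
   deliberately "fuzzy" discovery searches). Matching uses candidate
   refinement plus a KD-tree spatial index and is independent of sequence
   order; mirror-image embeddings are flagged via a chirality check.
4. **Hydrogen-bond filter.** Candidate triples are kept only if every base
   makes ≥ 2 base–base hydrogen bonds, judged with idealized polar
   hydrogens under HBPLUS-like default criteria (d(D···A) ≤ 3.9 Å,
   d(H···A) ≤ 2.5 Å, ∠DHA ≥ 90°, acceptor-antecedent angles ≥ 90°).
   Protonated variants (A-N1⁺, C-N3⁺) are searched on request.
5. **Classification.** Each hydrogen-bonded pair gets Leontis–Westhof edge
   labels (WC / H / S; the pyrimidine C-H edge counts as Hoogsteen) and a
   cis/trans glycosidic orientation; triples are named by a canonical
   geometric-family string (cis before trans, edges alphabetical, e.g.
   `Cis WC / WC – Trans H / WC`) and a stable composition code (`AGU1`).

## Worked example

The package ships a small starter pattern library measured from synthetic
fixtures and a generator for synthetic test structures, so the example
below needs no downloads:

```sh
# compose a U·A·U triple (Watson-Crick + Hoogsteen) with 5 decoy bases
cat > triple.spec <<EOF
BASE A
BASE U PAIR 1 WC WC cis
BASE U PAIR 1 WC H cis
EOF
triplescan make-fixture --spec triple.spec --seed 3 --decoys 5 --out demo.pdb

# survey it with the bundled library at the 1.7 Å tolerance
triplescan search --structure demo.pdb --patterns src/triplescan/data/patterns \
    --tolerance 1.7A --ignore-resolution --out -
```

which prints one admitted triple:

```
structure	residues	composition	code	family	contains_wc_pair	n_hbonds	pair_labels	patterns
demo	A:1;A:2;A:3	AUU	AUU1	Cis H / WC – Cis WC / WC	true	4	Cis WC / WC;Cis H / WC	uau-hoogsteen-wc
```

Reading: residues 1–3 form an A·U·U triple; the adenine binds one uridine
on its Watson–Crick edge (cis) and the other on its Hoogsteen edge, four
base–base hydrogen bonds in total; the triple contains a canonical
Watson–Crick pair. `triplescan inventory` prints per-structure counts by
family/code and the fraction of triples containing a Watson–Crick pair.

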