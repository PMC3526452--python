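# linchrom

Linearization of weighted ancestral gene adjacencies into a multichromosomal
genome whose chromosomes may be linear or circular.

## The problem

Ancestral genome reconstruction methods first infer a set of candidate
*adjacencies* — unordered pairs of markers (genes or gene-family
representatives) believed to have been neighbours in an ancestral genome —
each with a confidence weight derived from phylogenetic conservation.  The
candidate set is usually inconsistent: no single genome can realize all of
it.  The *linearization* step extracts a maximum-weight subset of adjacencies
that is consistent with a genome structure.

Requiring only linear chromosomes (the consecutive-ones property, C1P) or a
single circular chromosome (circular-ones, Ci1P) makes this NP-hard — it
contains maximum-weight path cover and TSP.  But the model that fits real
genomes, in particular bacteria with plasmids, allows *any number of
chromosomes, each linear or circular*, and optionally up to m(c) copies of
each marker c.  Under that relaxation the problem becomes polynomial for
adjacencies, and this package solves it exactly:

* A row subset of a degree-2 matrix is realizable by such a genome **iff**
  its graph is a *2m-matching*: every marker v keeps degree ≤ 2m(v).
* A maximum-weight 2m-matching is found by a gadget reduction to ordinary
  maximum-weight matching.  For each marker x build f(x) = 2·m(x) copy
  vertices; for each adjacency e = {x, y} of weight w(e) build ports e_x, e_y
  with edges {x_i, e_x}, {e_x, e_y}, {y_j, e_y}, all of weight w(e).  Then

      max-matching(G′) = W + max-2m-matching(G),   W = Σ_e w(e),

  an identity the pipeline re-verifies after every solve.
* The selected subgraph is decomposed into chromosomes by Eulerian trails:
  a connected component with all degrees even is one circular chromosome; a
  component with 2k odd-degree markers yields k linear chromosomes.

At row degree 3 (three-marker intervals) the same problem is NP-complete even
unweighted; the package ships exhaustive oracles for that boundary —
2,3-uniform hypergraph coverings by disjoint cycles and paths, and row
removal on degree-2/3 matrices — usable at toy scale for ground truth.

## Worked example

Six candidate adjacencies over markers `a`–`e`; marker `c` participates in
four of them:

```
a<TAB>b<TAB>5
b<TAB>c<TAB>4
c<TAB>a<TAB>3
c<TAB>d<TAB>6
d<TAB>e<TAB>2
e<TAB>c<TAB>1
```

With every marker restricted to one copy, `c` can keep at most two incident
adjacencies, so the optimum discards `{c,a}` (weight 3) and `{e,c}`
(weight 1):

```sh
$ linchrom run --adjacencies adj.tsv --out-genome genome.txt
kept 4/6 rows, weight 17 of 21; 0 circular + 1 linear chromosomes
$ cat genome.txt
#linchrom-genome v1
L e d c b a
```

The reported 17 of 21 is the selected weight versus the total input weight W;
the genome is a single linear chromosome e–d–c–b–a realizing the four kept
adjacencies.  Allowing two copies of `c` (`c<TAB>2` in a multiplicity file)
makes the full set consistent:

```sh
$ linchrom run --adjacencies adj.tsv --multiplicities mult.tsv --out-genome genome.txt
kept 6/6 rows, weight 21 of 21; 1 circular + 0 linear chromosomes
$ cat genome.txt
#linchrom-genome v1
C a b c d e c
```

One circular chromosome in which `c` occurs twice; all six adjacencies appear
consecutively exactly once.

Other subcommands: `linchrom simulate` (synthetic planted instances),
`linchrom check` (verify a genome realizes a row set), `linchrom oracle`
(brute-force small instances, including the degree-3 dialect).  All formats
are plain tab-separated text; see `docs/methods.md`.

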