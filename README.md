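# siftsmap

Structure-to-sequence cross-referencing for protein structures. Given a
PDBx/mmCIF structure and a reference sequence set (UniProtKB-style FASTA
plus taxonomy/provenance metadata), siftsmap

1. extracts each polymer entity's **sample sequence** (unobserved residues
   such as flexible loops are kept),
2. finds candidate reference matches by exhaustive local alignment with a
   90% sequence-identity cutoff,
3. ranks candidates with a bounded composite score in **[-50, 1300]**
   combining coverage x identity (x1000), a mismatch penalty
   (1 - mismatches/query length), taxonomy agreement (+200 species, +100
   genus, +50 family, +25 order) and dataset provenance (reviewed:
   +20 x annotation score; unreviewed: -50 + 10 x annotation score), with
   ties broken by PDB cross-reference counts,
4. builds residue-level one-to-one mappings from multiple non-overlapping
   local alignments, refined against experimentally observed backbone
   connectivity (C-N distance < 1.42 Å): short isolated matches inside
   extended alignment gaps are merged into the adjacent region when
   physically connected, or un-aligned into one contiguous gap otherwise,
5. persists hits/segments/residues into per-entry gzip CSVs and a
   single-file embedded database, and writes the annotations back into
   mmCIF (`_pdbx_sifts_unp_segments`, `_pdbx_sifts_xref_db`, extended
   `atom_site`).

Everything is testable offline: `siftsmap.fixtures` generates synthetic
structures, reference sets and alignment-artefact cases.

## CLI

Six subcommands cover the pipeline end to end:

```bash
siftsmap build_db refs.fasta taxonomy.tsv --annotation ann.tsv --xref xref.tsv -o idx/
siftsmap fasta_build entry.cif -o chains.fasta
siftsmap sequence_match --query-fasta chains.fasta --db idx/ \
    --lineage lineage.tsv --query-taxonomy qtax.tsv --out-dir hits/
siftsmap segments --mmcif entry.cif --ranked-hits hits/hits_ranked.tsv \
    --db idx/ --out-root out/
siftsmap db_load --root out/ --store mappings.db
siftsmap sifts2mmcif --mmcif entry.cif --entry-dir out/<entry>/ -o entry_sifts.cif
```

`segments --bypass-fasta ref.fasta` skips the search step and maps against
a user-supplied reference directly. Precomputed hits from an external
search tool can be fed in with `sequence_match --hits-tsv` (documented
fixed column order, see `siftsmap.reference_db.SEARCH_TSV_COLUMNS`).
Defaults (identity cutoff 0.9, connectivity threshold 1.42 Å, run-length
threshold 5, all score weights) are shown in `--help` for each subcommand
and can be set in a `key = value` config file passed with `--config`;
explicit flags win over the config file.

### File formats

* reference FASTA: `sp|ACC|NAME` / `tr|ACC|NAME` headers (`sp` = reviewed,
  `tr` = unreviewed, anything else = `other` with zero provenance score)
* taxonomy TSV: `identifier<TAB>taxid` (required for every reference)
* annotation TSV: `accession<TAB>score` (0-5); xref TSV: `accession<TAB>count`
* lineage TSV: `taxid<TAB>species<TAB>genus<TAB>family<TAB>order`
  (blank = rank absent)
* per-entry outputs: `sifts_xref_segment.csv.gz`, `sifts_xref_residue.csv.gz`
  (RFC 4180, lowercase booleans), plus `refinement_audit.json`

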