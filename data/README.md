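# Deposited genome data (not bundled)

The comparative checks against the two deposited dual-host-affiliated
insect-specific flavivirus genomes need their public GenBank records, which
are not redistributed here. With network access, fetch them once into this
directory:

```sh
curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=MF139576&rettype=fasta&retmode=text" > data/MF139576.fasta
curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=MF139575&rettype=fasta&retmode=text" > data/MF139575.fasta
```

For the relatedness checks, also fetch the complete polyproteins of the
closest relatives into a single protein FASTA `data/relatives.faa` with
record ids `DONV`, `ILOV`, `NOUV`, `NHUV` (GenBank accessions NC_016997,
NC_024805, NC_033715 and NC_024017 carry the polyprotein CDS), plus
`MMV`/`NANV` polyproteins translated from the genomes above (e.g. with
`prfscan annotate`).

Everything else in the test suite and the acceptance script is generated
synthetically and runs fully offline.
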