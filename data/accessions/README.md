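# data/accessions

Drop GenBank flat files here (named `<ACCESSION>.gb`) to enable the
paper-number acceptance tests and `scripts/acceptance.py` targets:

| file | record |
| --- | --- |
| `OR438928.gb` | phage ACA1 complete genome |
| `OR438929.gb` | phage ACA2 complete genome |
| `OR438030.gb` | prophage proACA1-A |
| `CP133569.gb` | host HL-AS1 chromosome |
| `CP133571.gb` | host HL-AS2 chromosome |
| `C5a.gb` | *Pseudoalteromonas* phage C5a genome |

This directory ships empty: the build environment had no route to NCBI or
the authors' mirror, so the records could not be bundled. Fetch them with
e.g.

```sh
efetch -db nuccore -id OR438928 -format gb > OR438928.gb
```
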