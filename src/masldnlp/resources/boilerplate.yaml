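# Section-heading markers for boilerplate stripping. Heading styles vary by
# hospital and era, so markers are data, not code: headers precede the
# diagnosis section, footers follow it. Matching is case-insensitive on the
# NFKC-normalized text; a marker is recognized at the start of a line.
diagnosis_headings:
  - "final diagnosis:"
  - "final pathologic diagnosis:"
  - "pathologic diagnosis:"
  - "diagnosis:"
  - "findings:"
  - "impression:"
  - "interpretation:"
  - "conclusion:"
header_headings:
  - "accession number:"
  - "accession:"
  - "specimen:"
  - "specimen received:"
  - "patient:"
  - "patient name:"
  - "mrn:"
  - "date of birth:"
  - "clinical data:"
  - "clinical history:"
  - "clinical information:"
  - "gross description:"
  - "gross:"
  - "specimen description:"
footer_headings:
  - "electronically signed"
  - "signed by"
  - "reported by"
  - "pathologist:"
  - "report electronically signed out"
  - "end of report"
gross_headings:
  - "gross description:"
  - "gross:"
  - "specimen description:"
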