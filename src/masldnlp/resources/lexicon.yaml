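# Curated histology lexicon: concept -> surface forms.
# Matching is case-insensitive on NFKC-normalized text with word boundaries;
# the longest match wins among overlapping candidates. Edit or replace this
# file to retarget the recognizer; no surface form may appear under two
# concepts.
steatosis:
  - steatosis
  - steatotic
  - macrovesicular steatosis
  - microvesicular steatosis
  - hepatic steatosis
  - fatty change
  - fatty liver
  - fatty metamorphosis
  - fatty infiltration
lobular_inflammation:
  - lobular inflammation
  - lobular chronic inflammation
  - lobular mixed inflammation
  - lobular inflammatory infiltrate
  - lobular inflammatory infiltrates
  - intralobular inflammation
  - lobular hepatitis
  - lobulitis
  - zone 3 inflammation
  - zone iii inflammation
  - centrilobular inflammation
  - lobular necroinflammation
  - lobular necroinflammatory activity
  - spotty lobular necrosis
portal_inflammation:
  - portal inflammation
  - portal chronic inflammation
  - portal inflammatory infiltrate
  - portal inflammatory infiltrates
  - portal lymphocytic infiltrate
  - periportal inflammation
  - interface hepatitis
  - interface activity
  - portal tract inflammation
ballooning:
  - ballooning
  - ballooned hepatocytes
  - ballooned cells
  - hepatocyte ballooning
  - hepatocellular ballooning
  - ballooning degeneration
  - balloon cell change
  - balloon cells
steatohepatitis:
  - steatohepatitis
  - nonalcoholic steatohepatitis
  - non-alcoholic steatohepatitis
  - nash
  - mash
  - fatty liver hepatitis
cirrhosis:
  - cirrhosis
  - cirrhotic
  - micronodular cirrhosis
  - macronodular cirrhosis
  - established cirrhosis
fibrosis_generic:
  - fibrosis
  - fibrotic
  - hepatic fibrosis
perisinusoidal_fibrosis:
  - perisinusoidal fibrosis
  - perisinusoidal
  - pericellular fibrosis
  - pericellular fibrosis in zone 3
  - zone 3 fibrosis
  - zone 3 pericellular fibrosis
  - zone iii fibrosis
  - sinusoidal fibrosis
  - perivenular fibrosis
  - chicken-wire fibrosis
  - chicken wire fibrosis
periportal_fibrosis:
  - periportal fibrosis
  - portal fibrosis
  - zone 1 fibrosis
  - zone i fibrosis
  - portal/periportal fibrosis
  - fibrosis in zone 1
  - portal tract fibrosis
  - portal expansion by fibrosis
bridging_fibrosis:
  - bridging fibrosis
  - bridging
  - fibrous septa
  - fibrous septum
  - septal fibrosis
  - bridging septa
  - portal-portal bridging
  - portal-central bridging
  - central-central bridging
nodularity:
  - nodularity
  - nodule formation
  - nodular architecture
  - regenerative nodules
  - regenerative nodule
  - parenchymal nodularity
  - cirrhotic nodules
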