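# Seven-attribute space used to characterize postnatal-depression innovations
# competing for implementation in a UK Primary Care Trust.  Level order defines
# the 1-based level indices used throughout the package; the regression
# constant is NOT an attribute (it lives on the fitted utility model).
- name: impact
  label: Impact on care
  levels:
    - Significant improvement
    - Moderate
    - Limited
- name: cost
  label: Costs
  levels:
    - Low
    - Moderate
    - High
- name: needs
  label: Local health needs
  levels:
    - Low prevalence
    - High prevalence
- name: standards
  label: Minimum standards
  levels:
    - "No, not meeting minimum standards."
    - "Yes, meeting minimum standards."
- name: evidence
  label: Strength of supporting evidence
  levels:
    - No supporting evidence.
    - Limited supporting evidence.
    - Moderate supporting evidence.
    - Strong supporting evidence.
- name: priority
  label: Priority
  levels:
    - National priority.
    - Local priority.
    - Both local and national priority.
- name: expertise
  label: Existence of local expertise
  levels:
    - "No, there is no local expertise."
    - "Yes, there is local expertise."
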