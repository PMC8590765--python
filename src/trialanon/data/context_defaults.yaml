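# Default context-risk checklist and probability tables.
#
# These are configuration values, not empirical claims: the attempt
# probabilities encode a conservative subjective mapping from the weakest
# control level to p(attempt), and p_breach is a placeholder annual
# health-data breach rate to be replaced with a current published figure.
groups:
  security:
    - access_control
    - audit_logs
    - analyst_screening
  privacy:
    - privacy_training
    - privacy_officer
  contractual:
    - confidentiality_agreement
    - data_use_agreement
p_attempt:
  high: 0.05     # all control groups strong
  medium: 0.20
  low: 0.40      # weakest-link level of any group
p_breach: 0.14   # placeholder annual breach probability
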