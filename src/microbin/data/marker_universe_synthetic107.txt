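# Synthetic stand-in universe of 107 single-copy marker gene ids.
# Replace with a real essential-single-copy-gene list (one id per line)
# to run against genuine marker-hit tables; downstream math depends only
# on the number of ids, not their identity.
SCG001
SCG002
SCG003
SCG004
SCG005
SCG006
SCG007
SCG008
SCG009
SCG010
SCG011
SCG012
SCG013
SCG014
SCG015
SCG016
SCG017
SCG018
SCG019
SCG020
SCG021
SCG022
SCG023
SCG024
SCG025
SCG026
SCG027
SCG028
SCG029
SCG030
SCG031
SCG032
SCG033
SCG034
SCG035
SCG036
SCG037
SCG038
SCG039
SCG040
SCG041
SCG042
SCG043
SCG044
SCG045
SCG046
SCG047
SCG048
SCG049
SCG050
SCG051
SCG052
SCG053
SCG054
SCG055
SCG056
SCG057
SCG058
SCG059
SCG060
SCG061
SCG062
SCG063
SCG064
SCG065
SCG066
SCG067
SCG068
SCG069
SCG070
SCG071
SCG072
SCG073
SCG074
SCG075
SCG076
SCG077
SCG078
SCG079
SCG080
SCG081
SCG082
SCG083
SCG084
SCG085
SCG086
SCG087
SCG088
SCG089
SCG090
SCG091
SCG092
SCG093
SCG094
SCG095
SCG096
SCG097
SCG098
SCG099
SCG100
SCG101
SCG102
SCG103
SCG104
SCG105
SCG106
SCG107
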