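sample_id,PARA,ASC,CAF,CPM,role
mix01,12.00,9.00,7.50,5.00,calibration
mix02,12.00,6.00,5.00,9.00,calibration
mix03,8.00,3.00,5.00,9.00,calibration
mix04,4.00,6.00,12.50,9.00,calibration
mix05,8.00,15.00,12.50,5.00,calibration
mix06,20.00,15.00,7.50,1.00,calibration
mix07,20.00,9.00,2.50,9.00,calibration
mix08,12.00,3.00,12.50,1.00,calibration
mix09,4.00,15.00,2.50,7.00,calibration
mix10,20.00,3.00,10.00,7.00,calibration
mix11,4.00,15.00,12.50,5.00,calibration
mix12,16.00,12.00,7.50,9.00,calibration
mix13,12.00,15.00,10.00,9.00,calibration
mix14,20.00,12.00,12.50,3.00,calibration
mix15,16.00,15.00,5.00,3.00,calibration
mix16,20.00,6.00,5.00,5.00,calibration
mix17,8.00,6.00,7.50,7.00,calibration
mix18,8.00,9.00,10.00,3.00,calibration
mix19,12.00,12.00,5.00,7.00,calibration
mix20,16.00,6.00,10.00,1.00,calibration
mix21,8.00,12.00,2.50,1.00,calibration
mix22,16.00,3.00,2.50,5.00,calibration
mix23,4.00,3.00,7.50,1.00,calibration
mix24,4.00,9.00,5.00,1.00,calibration
mix25,12.00,9.00,7.50,5.00,calibration
mix26,20.00,15.00,2.50,1.00,validation
mix27,4.00,15.00,2.50,9.00,validation
mix28,8.00,8.00,8.00,8.00,validation
mix29,12.00,9.00,7.50,5.00,validation
mix30,20.00,3.00,12.50,1.00,validation
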